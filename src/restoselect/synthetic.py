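"""Synthetic radiograph phantoms with class-specific texture statistics.

These images are statistical stand-ins for panoramic radiographs, not
anatomically realistic ones: each phantom is a smooth correlated-noise
background (a Gaussian random field with ~8 px correlation length) plus
one class-conditional bright component pattern that mimics how
high-density (metallic) restorations appear on radiographs:

* ``implant``    - one bright high-intensity disk with a hard edge
* ``crown``      - one bright compact blob with a smooth border
* ``bridge``     - an elongated bright bar
* ``filling``    - several small high-frequency bright speckles
* ``root_canal`` - thin bright near-vertical linear streaks

Component contrast scales linearly with ``effect_size`` (0 removes the
class signal entirely); a per-patient multiplicative background gain
makes images of the same patient correlated, which is what makes
patient-level splitting a meaningful leakage control on this data.
"""

from __future__ import annotations

import dataclasses
import zlib
from pathlib import Path

import numpy as np
from PIL import Image
from scipy.ndimage import gaussian_filter

from .dataio import CLASSES, ImageRecord, Manifest, write_manifest
from .exceptions import ConfigError, LabelError


@dataclasses.dataclass(frozen=True)
class PhantomSpec:
    """Parameters of the phantom dataset generator.

    ``class_priors`` follow the canonical label order
    ``(filling, implant, root_canal, bridge, crown)`` and default to a
    mildly imbalanced five-class mixture.  The default scale (24
    patients x 6 images = 144 images) loosely mirrors a small
    single-center study while staying fast on one CPU.
    """

    n_patients: int = 24
    images_per_patient: int = 6
    class_priors: tuple[float, ...] = (0.30, 0.15, 0.20, 0.15, 0.20)
    image_size: tuple[int, int] = (128, 128)  # (H, W)
    effect_size: float = 2.5
    noise_sd: float = 8.0
    background_mean: float = 90.0
    patient_gain_sd: float = 0.06
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.class_priors) != len(CLASSES):
            raise ConfigError(f"class_priors must have {len(CLASSES)} entries")
        if abs(sum(self.class_priors) - 1.0) > 1e-9:
            raise ConfigError("class_priors must sum to 1 within 1e-9")
        if min(self.class_priors) < 0:
            raise ConfigError("class_priors must be non-negative")
        if min(self.image_size) < 64:
            raise ConfigError("image dimensions must be >= 64")
        if self.effect_size < 0:
            raise ConfigError("effect_size must be >= 0")
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be >= 0")


def _patient_gain(patient_id: str, spec: PhantomSpec) -> float:
    """Deterministic per-patient background gain (stable across runs)."""
    key = zlib.crc32(patient_id.encode("utf-8"))
    rng = np.random.default_rng([spec.seed, key])
    return float(1.0 + spec.patient_gain_sd * rng.standard_normal())


def _background(spec: PhantomSpec, rng: np.random.Generator, gain: float) -> np.ndarray:
    """Gaussian random field: white noise blurred to ~8 px correlation."""
    h, w = spec.image_size
    field = gaussian_filter(rng.standard_normal((h, w)), sigma=4.0, mode="reflect")
    sd = field.std()
    if sd > 0:
        field /= sd
    return spec.background_mean * gain + spec.noise_sd * field


def _disk(h: int, w: int, cy: float, cx: float, r: float) -> np.ndarray:
    yy = np.arange(h)[:, None] - cy
    xx = np.arange(w)[None, :] - cx
    return (yy**2 + xx**2 <= r**2).astype(np.float64)


def _blob(h: int, w: int, cy: float, cx: float, sigma: float) -> np.ndarray:
    yy = np.arange(h)[:, None] - cy
    xx = np.arange(w)[None, :] - cx
    return np.exp(-(yy**2 + xx**2) / (2.0 * sigma**2))


def _segment(
    h: int, w: int, y0: float, x0: float, y1: float, x1: float, width: float
) -> np.ndarray:
    """Soft indicator of a thick line segment (distance-to-segment mask)."""
    yy, xx = np.mgrid[0:h, 0:w].astype(np.float64)
    dy, dx = y1 - y0, x1 - x0
    norm2 = dy**2 + dx**2
    t = np.clip(((yy - y0) * dy + (xx - x0) * dx) / max(norm2, 1e-12), 0.0, 1.0)
    dist2 = (yy - (y0 + t * dy)) ** 2 + (xx - (x0 + t * dx)) ** 2
    return (dist2 <= width**2).astype(np.float64)


def _components(
    label: str, spec: PhantomSpec, rng: np.random.Generator
) -> np.ndarray:
    """Class-conditional bright structures at unit effect size."""
    h, w = spec.image_size
    out = np.zeros((h, w), dtype=np.float64)
    if label == "implant":
        r = rng.uniform(9.0, 13.0)
        cy = rng.uniform(r + 2, h - r - 2)
        cx = rng.uniform(r + 2, w - r - 2)
        out += 26.0 * _disk(h, w, cy, cx, r)
    elif label == "crown":
        sigma = rng.uniform(5.0, 8.0)
        cy = rng.uniform(3 * sigma, h - 3 * sigma)
        cx = rng.uniform(3 * sigma, w - 3 * sigma)
        out += 34.0 * _blob(h, w, cy, cx, sigma)
    elif label == "bridge":
        length = rng.uniform(50.0, 80.0)
        half = rng.uniform(3.0, 5.0)
        cy = rng.uniform(10, h - 10)
        cx = rng.uniform(length / 2 + 2, w - length / 2 - 2)
        tilt = rng.uniform(-0.15, 0.15)
        y0 = cy - tilt * length / 2
        y1 = cy + tilt * length / 2
        out += 22.0 * _segment(h, w, y0, cx - length / 2, y1, cx + length / 2, half)
    elif label == "filling":
        n = int(rng.integers(6, 10))
        for _ in range(n):
            r = rng.uniform(1.0, 2.2)
            cy = rng.uniform(3, h - 3)
            cx = rng.uniform(3, w - 3)
            out += 30.0 * _disk(h, w, cy, cx, r)
    elif label == "root_canal":
        n = int(rng.integers(2, 4))
        for _ in range(n):
            length = rng.uniform(30.0, 55.0)
            angle = rng.uniform(-0.4, 0.4)  # radians off vertical
            y0 = rng.uniform(2, h - length - 2)
            x0 = rng.uniform(8, w - 8)
            y1 = y0 + length * np.cos(angle)
            x1 = x0 + length * np.sin(angle)
            out += 24.0 * _segment(h, w, y0, x0, y1, x1, 1.2)
    else:
        raise LabelError(
            f"unknown class {label!r}; valid labels are {list(CLASSES)}"
        )
    return out


def generate_phantom(
    class_label: str,
    patient_id: str,
    spec: PhantomSpec,
    seed: int,
    image_id: str | None = None,
) -> tuple[np.ndarray, ImageRecord]:
    """Generate one 8-bit phantom image plus its manifest record.

    Deterministic: the same ``(class_label, patient_id, spec, seed)``
    yields a bit-identical image.  The record's path is the conventional
    file name ``<image_id>.png``; :func:`generate_dataset` resolves it
    against the output directory when writing to disk.
    """
    if class_label not in CLASSES:
        raise LabelError(
            f"unknown class {class_label!r}; valid labels are {list(CLASSES)}"
        )
    rng = np.random.default_rng([int(seed), CLASSES.index(class_label)])
    gain = _patient_gain(patient_id, spec)
    img = _background(spec, rng, gain)
    img += spec.effect_size * _components(class_label, spec, rng)
    img = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    if image_id is None:
        image_id = f"{patient_id}_{class_label}_{seed}"
    h, w = spec.image_size
    record = ImageRecord(
        image_id=image_id,
        patient_id=patient_id,
        path=Path(f"{image_id}.png"),
        label=class_label,
        width=w,
        height=h,
    )
    return img, record


def generate_dataset(spec: PhantomSpec, out_dir: str | Path) -> Manifest:
    """Generate a full phantom dataset: PNG images plus ``manifest.csv``.

    Each image receives one dominant label drawn from ``class_priors``;
    every patient contributes exactly ``images_per_patient`` images.
    """
    if spec.n_patients < 2:
        raise ConfigError("need at least 2 patients to allow any split")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    label_rng = np.random.default_rng([spec.seed, 2**20])
    priors = np.asarray(spec.class_priors, dtype=float)
    records = []
    for i in range(spec.n_patients):
        patient_id = f"P{i:03d}"
        for j in range(spec.images_per_patient):
            label = CLASSES[int(label_rng.choice(len(CLASSES), p=priors))]
            image_id = f"img_{i:03d}_{j:02d}"
            img_seed = int(
                np.random.default_rng([spec.seed, i, j]).integers(2**31)
            )
            img, rec = generate_phantom(
                label, patient_id, spec, img_seed, image_id=image_id
            )
            img_path = out_dir / rec.path
            Image.fromarray(img, mode="L").save(img_path)
            records.append(dataclasses.replace(rec, path=img_path))
    manifest = Manifest(tuple(records))
    write_manifest(manifest, out_dir / "manifest.csv")
    return manifest
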