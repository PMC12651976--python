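"""Shared fixtures and independent brute-force oracles."""

from __future__ import annotations

import numpy as np
import pytest

from restoselect import EnhanceConfig, PhantomSpec, generate_dataset
from restoselect.texture import compute_feature_table


# ---------------------------------------------------------------------------
# Independent oracles (pure-python enumeration; no shared code paths with
# the implementation under test).
# ---------------------------------------------------------------------------

ORACLE_OFFSETS = {0: (0, 1), 45: (-1, 1), 90: (-1, 0), 135: (-1, -1)}


def oracle_glcm(q: np.ndarray, levels: int, angle: int) -> np.ndarray:
    """Brute-force symmetric normalized GLCM by explicit pair enumeration."""
    dr, dc = ORACLE_OFFSETS[angle]
    h, w = q.shape
    m = np.zeros((levels, levels), dtype=float)
    for r in range(h):
        for c in range(w):
            r2, c2 = r + dr, c + dc
            if 0 <= r2 < h and 0 <= c2 < w:
                m[q[r, c], q[r2, c2]] += 1.0
    m = m + m.T
    return m / m.sum()


def oracle_descriptors(p: np.ndarray) -> tuple[float, float, float, float, float]:
    """Descriptor definitions written out as explicit double loops."""
    n = p.shape[0]
    contrast = sum(p[i, j] * (i - j) ** 2 for i in range(n) for j in range(n))
    asm = sum(p[i, j] ** 2 for i in range(n) for j in range(n))
    hom = sum(p[i, j] / (1 + abs(i - j)) for i in range(n) for j in range(n))
    ent = -sum(
        p[i, j] * np.log2(p[i, j])
        for i in range(n)
        for j in range(n)
        if p[i, j] > 0
    )
    mx = sum(i * p[i, j] for i in range(n) for j in range(n))
    my = sum(j * p[i, j] for i in range(n) for j in range(n))
    vx = sum((i - mx) ** 2 * p[i, j] for i in range(n) for j in range(n))
    vy = sum((j - my) ** 2 * p[i, j] for i in range(n) for j in range(n))
    if vx * vy == 0:
        corr = 1.0
    else:
        corr = sum(
            (i - mx) * (j - my) * p[i, j] for i in range(n) for j in range(n)
        ) / np.sqrt(vx * vy)
    return float(contrast), float(corr), float(asm), float(hom), float(ent)


def oracle_features(img: np.ndarray, levels: int) -> np.ndarray:
    """25-vector oracle: quantize, enumerate pairs, average over angles."""
    lo, hi = img.min(), img.max()
    if hi == lo:
        q = np.zeros(img.shape, dtype=int)
    else:
        x = (img.astype(float) - lo) / (hi - lo)
        q = np.minimum((x * levels).astype(int), levels - 1)
    per_angle = [
        oracle_descriptors(oracle_glcm(q, levels, a)) for a in (0, 45, 90, 135)
    ]
    out = []
    for d in range(5):
        vals = [per_angle[a][d] for a in range(4)]
        out.extend(vals)
        out.append(float(np.mean(vals)))
    return np.asarray(out)


class PlantedSubsetFitness:
    """Deterministic toy wrapper-accuracy with one known best subset.

    Accuracy rises with the fraction of planted features included and
    falls mildly with each noise feature, so the brute-force optimum of
    F = 0.9 Acc + 0.1 (1 - Fr) is exactly the planted mask.
    """

    def __init__(self, planted: np.ndarray):
        self.planted = np.asarray(planted, dtype=bool)
        self.d = self.planted.size

    def accuracy(self, mask: np.ndarray) -> float:
        mask = np.asarray(mask, dtype=bool)
        hits = np.sum(mask & self.planted) / self.planted.sum()
        false = np.sum(mask & ~self.planted) / max(self.d - self.planted.sum(), 1)
        return float(np.clip(0.3 + 0.7 * hits - 0.15 * false, 0.0, 1.0))


def planted_feature_table(
    seed: int, n_per_class: int = 24, d: int = 25, shift: float = 2.0
) -> tuple[np.ndarray, np.ndarray]:
    """Feature matrix with the first 5 columns informative (2 SD shift)."""
    rng = np.random.default_rng(seed)
    X, y = [], []
    for c in range(5):
        Z = rng.standard_normal((n_per_class, d))
        Z[:, c] += shift
        X.append(Z)
        y.extend([f"class{c}"] * n_per_class)
    return np.vstack(X), np.asarray(y)


# ---------------------------------------------------------------------------
# Dataset fixtures
# ---------------------------------------------------------------------------


@pytest.fixture(scope="session")
def phantom_dir(tmp_path_factory):
    """Small phantom dataset on disk (12 patients x 4 images, strong effect)."""
    out = tmp_path_factory.mktemp("phantom")
    spec = PhantomSpec(
        n_patients=14, images_per_patient=5, effect_size=3.0, seed=7
    )
    manifest = generate_dataset(spec, out)
    return out, spec, manifest


@pytest.fixture(scope="session")
def phantom_manifest(phantom_dir):
    return phantom_dir[2]


@pytest.fixture(scope="session")
def phantom_features(phantom_manifest):
    """Feature table for the small phantom dataset (no enhancement)."""
    return compute_feature_table(phantom_manifest)


@pytest.fixture(scope="session")
def default_phantom(tmp_path_factory):
    """The generator's default study conditions (24 patients x 6 images)."""
    out = tmp_path_factory.mktemp("phantom_default")
    spec = PhantomSpec(seed=7)
    manifest = generate_dataset(spec, out)
    table = compute_feature_table(
        manifest, enhance_cfg=EnhanceConfig(crop_to=None)
    )
    return spec, manifest, table
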