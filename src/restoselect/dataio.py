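"""Dataset manifests, image loading and feature tables.

The on-disk artifacts are deliberately plain: a manifest is a CSV with
columns ``image_id, patient_id, path, label``; images are single-channel
PNG/TIFF/JPEG at 8 or 16 bit; feature tables are CSV with a canonical
column ordering.  Labels use lower-snake-case tokens; display names used
in clinical reporting are kept in :data:`DISPLAY_NAMES`.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from PIL import Image

from .exceptions import (
    DuplicationError,
    ImageIOError,
    LabelError,
    SchemaError,
)

#: Closed five-class label set, in canonical order.
CLASSES: tuple[str, ...] = ("filling", "implant", "root_canal", "bridge", "crown")

#: Mapping from label tokens to the display names used in reports.
DISPLAY_NAMES: dict[str, str] = {
    "filling": "Filling",
    "implant": "Implant",
    "root_canal": "Root-canal treatment",
    "bridge": "Fixed partial denture (bridge)",
    "crown": "Crown",
}

#: The five texture descriptors, in canonical (descriptor-major) order.
FEATURE_DESCRIPTORS: tuple[str, ...] = (
    "Contrast",
    "Correlation",
    "ASM",
    "Homogeneity",
    "Entropy",
)

#: Co-occurrence angles in degrees.
ANGLES_DEG: tuple[int, ...] = (0, 45, 90, 135)

#: Canonical 25 feature names: descriptor-major, within each descriptor the
#: four angles followed by the bare descriptor name for the angle average
#: (e.g. ``Contrast0, Contrast45, Contrast90, Contrast135, Contrast``).
FEATURE_NAMES: tuple[str, ...] = tuple(
    name
    for d in FEATURE_DESCRIPTORS
    for name in [f"{d}{a}" for a in ANGLES_DEG] + [d]
)

_MANIFEST_COLUMNS = ("image_id", "patient_id", "path", "label")
_FEATURE_TABLE_COLUMNS = ("image_id", "patient_id", "label") + FEATURE_NAMES


@dataclasses.dataclass(frozen=True)
class ImageRecord:
    """One grayscale radiograph with its patient id and dominant label."""

    image_id: str
    patient_id: str
    path: Path
    label: str
    width: int | None = None
    height: int | None = None

    def __post_init__(self) -> None:
        if self.label not in CLASSES:
            raise LabelError(
                f"unknown label {self.label!r}; valid labels are {list(CLASSES)}"
            )


@dataclasses.dataclass(frozen=True)
class Manifest:
    """Ordered collection of :class:`ImageRecord` with unique image ids."""

    records: tuple[ImageRecord, ...]

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for rec in self.records:
            if rec.image_id in seen:
                raise DuplicationError(f"duplicate image_id {rec.image_id!r}")
            seen.add(rec.image_id)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def patients(self) -> tuple[str, ...]:
        """Distinct patient ids in first-appearance order."""
        out: dict[str, None] = {}
        for rec in self.records:
            out.setdefault(rec.patient_id, None)
        return tuple(out)

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(rec.label for rec in self.records)

    def subset(self, patient_ids: Iterable[str]) -> "Manifest":
        wanted = set(patient_ids)
        return Manifest(
            tuple(r for r in self.records if r.patient_id in wanted)
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "image_id": [r.image_id for r in self.records],
                "patient_id": [r.patient_id for r in self.records],
                "path": [str(r.path) for r in self.records],
                "label": [r.label for r in self.records],
            }
        )


def read_manifest(path: str | Path, require_files: bool = True) -> Manifest:
    """Read and validate a manifest CSV.

    Parameters
    ----------
    path:
        CSV file with header columns ``image_id, patient_id, path, label``.
    require_files:
        If true (default), every referenced image file must exist.
        Relative paths are resolved against the manifest's directory.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype=str)
    missing = [c for c in _MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(
            f"manifest {path} is missing required column(s) {missing}; "
            f"expected header {list(_MANIFEST_COLUMNS)}"
        )
    records = []
    for row in df.itertuples(index=False):
        img_path = Path(row.path)
        if not img_path.is_absolute():
            img_path = path.parent / img_path
        if require_files and not img_path.is_file():
            raise ImageIOError(
                f"image file {img_path} referenced by {row.image_id!r} does not exist"
            )
        records.append(
            ImageRecord(
                image_id=str(row.image_id),
                patient_id=str(row.patient_id),
                path=img_path,
                label=str(row.label),
            )
        )
    return Manifest(tuple(records))


def write_manifest(manifest: Manifest, path: str | Path) -> Path:
    """Write a manifest to CSV with the fixed header; returns the path."""
    path = Path(path)
    manifest.to_dataframe().to_csv(path, index=False)
    return path


@dataclasses.dataclass(frozen=True)
class LoadedImage:
    """An integer grayscale pixel matrix plus its bit depth (8 or 16)."""

    pixels: np.ndarray
    bit_depth: int

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]


def load_image(source: ImageRecord | str | Path) -> LoadedImage:
    """Load a grayscale image as an integer matrix at native bit depth.

    Multi-channel inputs are converted to luminance (ITU-R 601 weights via
    Pillow's ``L`` mode); a uniform gray RGB image therefore maps to its
    own gray level.  No intensity normalization happens here — any
    rescaling downstream is explicit.
    """
    path = Path(source.path if isinstance(source, ImageRecord) else source)
    if not path.is_file() or path.stat().st_size == 0:
        raise ImageIOError(f"cannot read image file {path}")
    try:
        with Image.open(path) as im:
            if im.mode in ("I;16", "I;16B", "I;16L", "I"):
                arr = np.asarray(im, dtype=np.uint16)
                depth = 16
            elif im.mode == "L":
                arr = np.asarray(im, dtype=np.uint8)
                depth = 8
            else:
                arr = np.asarray(im.convert("L"), dtype=np.uint8)
                depth = 8
    except ImageIOError:
        raise
    except OSError as exc:
        raise ImageIOError(f"cannot read image file {path}: {exc}") from exc
    if arr.ndim != 2 or arr.size == 0:
        raise ImageIOError(f"image {path} is not a non-empty 2-D grayscale matrix")
    return LoadedImage(pixels=arr, bit_depth=depth)


@dataclasses.dataclass
class FeatureTable:
    """Per-image texture features with label and patient columns.

    Wraps a :class:`pandas.DataFrame` whose columns are exactly
    ``image_id, patient_id, label`` followed by the 25 canonical feature
    names in :data:`FEATURE_NAMES`.
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        cols = tuple(self.frame.columns)
        if cols != _FEATURE_TABLE_COLUMNS:
            missing = [c for c in _FEATURE_TABLE_COLUMNS if c not in cols]
            extra = [c for c in cols if c not in _FEATURE_TABLE_COLUMNS]
            raise SchemaError(
                "feature table columns do not match the canonical schema; "
                f"missing {missing}, unexpected {extra}"
            )
        bad = set(self.frame["label"]) - set(CLASSES)
        if bad:
            raise LabelError(f"unknown label(s) {sorted(bad)} in feature table")
        if self.frame[list(FEATURE_NAMES)].isna().any().any():
            raise SchemaError("feature table contains missing values")
        if self.frame["image_id"].duplicated().any():
            dup = self.frame["image_id"][self.frame["image_id"].duplicated()].iloc[0]
            raise DuplicationError(f"duplicate image_id {dup!r} in feature table")

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def X(self) -> np.ndarray:
        """(n, 25) float feature matrix in canonical column order."""
        return self.frame[list(FEATURE_NAMES)].to_numpy(dtype=float)

    @property
    def y(self) -> np.ndarray:
        return self.frame["label"].to_numpy()

    @property
    def image_ids(self) -> np.ndarray:
        return self.frame["image_id"].to_numpy()

    @property
    def patient_ids(self) -> np.ndarray:
        return self.frame["patient_id"].to_numpy()

    @property
    def patients(self) -> tuple[str, ...]:
        out: dict[str, None] = {}
        for p in self.frame["patient_id"]:
            out.setdefault(p, None)
        return tuple(out)

    def subset_patients(self, patient_ids: Iterable[str]) -> "FeatureTable":
        wanted = set(patient_ids)
        sub = self.frame[self.frame["patient_id"].isin(wanted)]
        return FeatureTable(sub.reset_index(drop=True))

    @classmethod
    def from_rows(
        cls,
        image_ids: Sequence[str],
        patient_ids: Sequence[str],
        labels: Sequence[str],
        features: np.ndarray,
    ) -> "FeatureTable":
        features = np.asarray(features, dtype=float)
        if features.shape != (len(image_ids), len(FEATURE_NAMES)):
            raise SchemaError(
                f"feature matrix shape {features.shape} does not match "
                f"({len(image_ids)}, {len(FEATURE_NAMES)})"
            )
        frame = pd.DataFrame(
            {"image_id": image_ids, "patient_id": patient_ids, "label": labels}
        )
        for j, name in enumerate(FEATURE_NAMES):
            frame[name] = features[:, j]
        return cls(frame)


def write_feature_table(table: FeatureTable, path: str | Path) -> Path:
    """Write a feature table to CSV, lossless to >= 12 significant digits."""
    path = Path(path)
    table.frame.to_csv(path, index=False, float_format="%.17g")
    return path


def read_feature_table(path: str | Path) -> FeatureTable:
    """Read a feature table CSV, validating the canonical header."""
    path = Path(path)
    df = pd.read_csv(
        path, dtype={"image_id": str, "patient_id": str, "label": str}
    )
    missing = [c for c in _FEATURE_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(
            f"feature table {path} is missing column(s) {missing}"
        )
    return FeatureTable(df[list(_FEATURE_TABLE_COLUMNS)])
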