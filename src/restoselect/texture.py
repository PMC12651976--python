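"""Global GLCM texture descriptors.

Each image is reduced to a 25-dimensional descriptor vector: five
Haralick-style statistics (contrast, correlation, energy/ASM,
homogeneity, entropy) of the whole-image gray-level co-occurrence matrix
at displacement d=1 along 0deg, 45deg, 90deg and 135deg, plus the
arithmetic mean of each statistic over the four angles.  Matrices are
symmetrized (each ordered pixel pair is counted in both directions) and
normalized to probabilities, making the descriptors rotation-direction
invariant.

Pixel intensities are first min-max rescaled per image to [0, 1] and
uniformly binned into 64 gray levels; a constant image maps entirely to
level 0.  Feature columns (not pixels) are z-score standardized before
classification, with the standardizer fitted on training rows only.

Angle convention: offsets in (row, col) are 0deg=(0,+1), 45deg=(-1,+1),
90deg=(-1,0), 135deg=(-1,-1); rows increase downward, so 45deg is the
up-right diagonal.  ``skimage.feature.graycomatrix`` measures angles
with rows increasing in the sine direction, so under symmetrization our
45deg corresponds to its 3*pi/4 and our 135deg to its pi/4.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
from skimage.feature import graycomatrix

from .dataio import (
    ANGLES_DEG,
    FEATURE_NAMES,
    FeatureTable,
    LoadedImage,
    Manifest,
    load_image,
)
from .exceptions import ConfigError, DimensionError, SchemaError
from .preprocess import EnhanceConfig, enhance

#: Map from our angle convention (degrees) to the skimage angle (radians)
#: that realizes the same symmetric co-occurrence set.
_SKIMAGE_ANGLE = {0: 0.0, 45: 3 * np.pi / 4, 90: np.pi / 2, 135: np.pi / 4}

#: (row, col) displacement per angle at unit distance (used by tests/oracles).
ANGLE_OFFSETS = {0: (0, 1), 45: (-1, 1), 90: (-1, 0), 135: (-1, -1)}


@dataclasses.dataclass(frozen=True)
class GlcmConfig:
    """GLCM parameters: 64 levels, unit displacement, four fixed angles."""

    levels: int = 64
    distance: int = 1
    angles: tuple[int, ...] = ANGLES_DEG
    symmetric: bool = True
    normalize: bool = True

    def __post_init__(self) -> None:
        if self.levels < 2:
            raise ConfigError("levels must be >= 2")
        if self.distance < 1:
            raise ConfigError("distance must be >= 1")
        if tuple(self.angles) != ANGLES_DEG:
            raise ConfigError(f"angles are fixed to {ANGLES_DEG}")


def quantize(img: np.ndarray, levels: int = 64) -> np.ndarray:
    """Min-max rescale to [0, 1] then uniform-bin into ``levels`` levels.

    Bin index is ``floor(x * levels)`` clipped to ``levels - 1``, so the
    minimum maps to 0, the maximum to ``levels - 1``, and a constant
    image maps entirely to level 0.
    """
    img = np.asarray(img)
    if img.size == 0:
        raise DimensionError("cannot quantize an empty image")
    lo = img.min()
    hi = img.max()
    if hi == lo:
        return np.zeros(img.shape, dtype=np.uint16)
    x = (img.astype(np.float64) - lo) / (hi - lo)
    q = np.minimum((x * levels).astype(np.int64), levels - 1)
    return q.astype(np.uint16)


def glcm(qimg: np.ndarray, cfg: GlcmConfig, angle: int) -> np.ndarray:
    """Symmetric, normalized co-occurrence matrix for one angle.

    Ordered pixel pairs at the angle's displacement are counted, the
    transpose added, and the matrix normalized to sum 1.  Pairs are
    truncated at image borders (no wraparound or padding).
    """
    qimg = np.asarray(qimg)
    if angle not in _SKIMAGE_ANGLE:
        raise ConfigError(f"angle must be one of {sorted(_SKIMAGE_ANGLE)}")
    if qimg.max(initial=0) >= cfg.levels:
        raise DimensionError("quantized image has values >= levels")
    dr, dc = ANGLE_OFFSETS[angle]
    h, w = qimg.shape
    if h <= abs(dr) * cfg.distance or w <= abs(dc) * cfg.distance:
        raise DimensionError(
            f"image {w}x{h} has no pixel pairs at distance {cfg.distance}, angle {angle}"
        )
    m = graycomatrix(
        qimg.astype(np.uint16),
        distances=[cfg.distance],
        angles=[_SKIMAGE_ANGLE[angle]],
        levels=cfg.levels,
        symmetric=cfg.symmetric,
        normed=cfg.normalize,
    )
    return m[:, :, 0, 0].astype(np.float64)


def descriptors(p: np.ndarray) -> tuple[float, float, float, float, float]:
    """(contrast, correlation, ASM, homogeneity, entropy) of a GLCM.

    * contrast     = sum p(i,j) (i-j)^2
    * correlation  = sum p(i,j) (i-mu_x)(j-mu_y) / (sigma_x sigma_y),
      defined as 1 when sigma_x * sigma_y = 0 (a constant texture is
      perfectly predictable)
    * ASM (energy) = sum p(i,j)^2
    * homogeneity  = sum p(i,j) / (1 + |i-j|)
    * entropy      = -sum p(i,j) log2 p(i,j) over nonzero entries (bits)
    """
    p = np.asarray(p, dtype=np.float64)
    n = p.shape[0]
    i = np.arange(n, dtype=np.float64)
    diff = i[:, None] - i[None, :]
    contrast = float(np.sum(p * diff**2))
    px = p.sum(axis=1)
    py = p.sum(axis=0)
    mx = float(np.dot(i, px))
    my = float(np.dot(i, py))
    vx = float(np.dot((i - mx) ** 2, px))
    vy = float(np.dot((i - my) ** 2, py))
    denom = np.sqrt(vx * vy)
    if denom == 0.0:
        correlation = 1.0
    else:
        correlation = float(
            np.sum(p * (i[:, None] - mx) * (i[None, :] - my)) / denom
        )
    asm = float(np.sum(p**2))
    homogeneity = float(np.sum(p / (1.0 + np.abs(diff))))
    nz = p[p > 0]
    entropy = float(-np.sum(nz * np.log2(nz)))
    return contrast, correlation, asm, homogeneity, entropy


def extract_features(img: np.ndarray, cfg: GlcmConfig | None = None) -> np.ndarray:
    """25-vector of texture features in the canonical column order.

    For each descriptor: four per-angle values followed by their
    arithmetic mean (the bare-named "angle average" slot).
    """
    if cfg is None:
        cfg = GlcmConfig()
    q = quantize(img, cfg.levels)
    per_angle = np.array(
        [descriptors(glcm(q, cfg, a)) for a in cfg.angles]
    )  # (4 angles, 5 descriptors)
    out = []
    for d in range(per_angle.shape[1]):
        vals = per_angle[:, d]
        out.extend(vals)
        out.append(vals.mean())
    return np.asarray(out, dtype=np.float64)


def compute_feature_table(
    manifest: Manifest,
    cfg: GlcmConfig | None = None,
    enhance_cfg: EnhanceConfig | None = None,
) -> FeatureTable:
    """Load, optionally enhance, and featurize every manifest image.

    ``enhance_cfg=None`` skips enhancement entirely (features on raw
    pixels); pass :class:`EnhanceConfig` to run crop -> HE -> CLAHE first.
    """
    feats = np.empty((len(manifest), len(FEATURE_NAMES)), dtype=np.float64)
    for k, rec in enumerate(manifest):
        img = load_image(rec).pixels
        if enhance_cfg is not None:
            img = enhance(img, enhance_cfg)
        feats[k] = extract_features(img, cfg)
    return FeatureTable.from_rows(
        [r.image_id for r in manifest],
        [r.patient_id for r in manifest],
        [r.label for r in manifest],
        feats,
    )


@dataclasses.dataclass
class Standardizer:
    """Per-column z-score transform with training-only statistics.

    Columns with zero training variance map to 0 everywhere.  ``fit``
    must only ever see training rows; applying to a table whose columns
    differ from those seen at fit raises :class:`SchemaError`.
    """

    columns: tuple[str, ...] | None = None
    mean_: np.ndarray | None = None
    sd_: np.ndarray | None = None

    def fit(
        self, X: np.ndarray, columns: Sequence[str] = FEATURE_NAMES
    ) -> "Standardizer":
        X = np.asarray(X, dtype=float)
        self.columns = tuple(columns)
        if X.shape[1] != len(self.columns):
            raise SchemaError(
                f"feature matrix has {X.shape[1]} columns, expected {len(self.columns)}"
            )
        self.mean_ = X.mean(axis=0)
        self.sd_ = X.std(axis=0, ddof=0)
        return self

    def transform(
        self, X: np.ndarray, columns: Sequence[str] = FEATURE_NAMES
    ) -> np.ndarray:
        if self.mean_ is None or self.sd_ is None or self.columns is None:
            raise SchemaError("standardizer has not been fitted")
        if tuple(columns) != self.columns:
            raise SchemaError("column mismatch between fit and apply")
        X = np.asarray(X, dtype=float)
        sd = np.where(self.sd_ == 0, 1.0, self.sd_)
        out = (X - self.mean_) / sd
        out[:, self.sd_ == 0] = 0.0
        return out

    def fit_transform(
        self, X: np.ndarray, columns: Sequence[str] = FEATURE_NAMES
    ) -> np.ndarray:
        return self.fit(X, columns).transform(X, columns)


def zscore_fit(train: FeatureTable) -> Standardizer:
    """Fit a feature-column standardizer on a training table only."""
    return Standardizer().fit(train.X, FEATURE_NAMES)


def zscore_apply(std: Standardizer, table: FeatureTable) -> np.ndarray:
    """Apply a fitted standardizer to a table's feature matrix."""
    return std.transform(table.X, FEATURE_NAMES)
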