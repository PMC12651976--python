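"""Radiograph enhancement: center crop, global HE, then CLAHE.

The enhancement chain used for panoramic radiographs is a centered crop
that removes non-diagnostic peripheral margins (2775x1504 sources are
cropped to 1700x880 by default), global histogram equalization, and
contrast-limited adaptive histogram equalization (clip limit 2.0, 8x8
tile grid).

Conventions
-----------
* Global HE uses the textbook CDF mapping to the full bit range:
  ``out = round((cdf(v) - cdf_min) / (N - cdf_min) * (L - 1))`` where
  ``cdf_min`` is the CDF at the lowest occupied gray level.  The mapping
  is monotone, so pixel rank order is preserved.
* The CLAHE clip limit is the common "multiple of the uniform tile
  histogram height" convention: a tile of ``n`` pixels over ``L`` bins is
  clipped at ``clip * n / L`` counts, with the excess redistributed
  uniformly.  Tile mappings use the same full-range CDF convention as
  global HE and are blended by bilinear interpolation between tile
  centers, so in the limit of one tile and no clipping CLAHE reduces to
  global HE.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .exceptions import ConfigError, DimensionError


@dataclasses.dataclass(frozen=True)
class EnhanceConfig:
    """Parameters of the enhancement chain.

    ``crop_to`` is (width, height); cropping is applied only when the
    source exceeds the target in both dimensions, so small synthetic
    phantoms pass through at full frame.
    """

    crop_to: tuple[int, int] | None = (1700, 880)
    clahe_clip: float = 2.0
    clahe_grid: tuple[int, int] = (8, 8)
    apply_he: bool = True
    apply_clahe: bool = True

    def __post_init__(self) -> None:
        if self.clahe_clip <= 0:
            raise ConfigError("clahe_clip must be > 0")
        if min(self.clahe_grid) < 1:
            raise ConfigError("clahe_grid dimensions must be >= 1")
        if self.crop_to is not None and min(self.crop_to) < 1:
            raise ConfigError("crop_to dimensions must be >= 1")


def _check_int_gray(img: np.ndarray) -> np.ndarray:
    img = np.asarray(img)
    if img.ndim != 2 or img.size == 0:
        raise DimensionError("expected a non-empty 2-D grayscale matrix")
    if not np.issubdtype(img.dtype, np.integer):
        raise DimensionError("expected an integer grayscale matrix")
    return img


def _n_levels(img: np.ndarray) -> int:
    """Number of representable gray levels (256 or 65536) for the dtype."""
    return int(np.iinfo(img.dtype).max) + 1


def crop_center(img: np.ndarray, target: tuple[int, int]) -> np.ndarray:
    """Centered crop to ``target`` = (width, height).

    Offsets are ``floor((source - target) / 2)`` in each axis; a target
    exceeding the source raises (no padding is ever performed).
    """
    img = _check_int_gray(img)
    tw, th = target
    h, w = img.shape
    if tw > w or th > h:
        raise DimensionError(
            f"crop target {tw}x{th} exceeds source {w}x{h}; padding is not supported"
        )
    left = (w - tw) // 2
    top = (h - th) // 2
    return img[top : top + th, left : left + tw]


def _he_lut(hist: np.ndarray, levels_out: int) -> np.ndarray:
    """Full-range CDF mapping LUT for one histogram."""
    cdf = np.cumsum(hist)
    total = cdf[-1]
    occupied = np.nonzero(hist)[0]
    cdf_min = cdf[occupied[0]] if occupied.size else 0
    if total == cdf_min:  # single occupied level: identity on that level
        return np.arange(hist.size)
    lut = np.rint((cdf - cdf_min) / (total - cdf_min) * (levels_out - 1))
    return np.clip(lut, 0, levels_out - 1).astype(np.int64)


def hist_equalize(img: np.ndarray) -> np.ndarray:
    """Global histogram equalization at native bit depth.

    A constant image is returned unchanged (single-bin histogram).
    """
    img = _check_int_gray(img)
    levels = _n_levels(img)
    hist = np.bincount(img.ravel(), minlength=levels)
    if np.count_nonzero(hist) <= 1:
        return img.copy()
    lut = _he_lut(hist, levels)
    return lut[img].astype(img.dtype)


def clahe(
    img: np.ndarray,
    clip: float = 2.0,
    grid: tuple[int, int] = (8, 8),
) -> np.ndarray:
    """Contrast-limited adaptive histogram equalization.

    Parameters
    ----------
    img:
        Integer grayscale matrix, at least as large as ``grid`` in each
        dimension.
    clip:
        Clip limit as a multiple of the uniform tile histogram height;
        each tile histogram is clipped at ``clip * n_tile / L`` counts
        and the excess redistributed uniformly over all bins.
    grid:
        Tile grid as (rows, cols).  Per-tile equalization LUTs are
        blended bilinearly between tile centers; beyond the outermost
        tile centers the nearest tile mapping is used.
    """
    img = _check_int_gray(img)
    gr, gc = int(grid[0]), int(grid[1])
    h, w = img.shape
    if h < gr or w < gc:
        raise DimensionError(f"image {w}x{h} is smaller than the {gc}x{gr} tile grid")
    levels = _n_levels(img)

    row_edges = np.linspace(0, h, gr + 1).astype(int)
    col_edges = np.linspace(0, w, gc + 1).astype(int)
    luts = np.empty((gr, gc, levels), dtype=np.float64)
    for i in range(gr):
        for j in range(gc):
            tile = img[row_edges[i] : row_edges[i + 1], col_edges[j] : col_edges[j + 1]]
            hist = np.bincount(tile.ravel(), minlength=levels).astype(np.float64)
            limit = clip * tile.size / levels
            if np.isfinite(limit):
                excess = np.maximum(hist - limit, 0.0).sum()
                hist = np.minimum(hist, limit) + excess / levels
            luts[i, j] = _he_lut_float(hist, levels)

    # Bilinear blend between tile-center mappings.
    row_centers = (row_edges[:-1] + row_edges[1:] - 1) / 2.0
    col_centers = (col_edges[:-1] + col_edges[1:] - 1) / 2.0
    ri = np.interp(np.arange(h), row_centers, np.arange(gr))
    ci = np.interp(np.arange(w), col_centers, np.arange(gc))
    r0 = np.floor(ri).astype(int)
    c0 = np.floor(ci).astype(int)
    r1 = np.minimum(r0 + 1, gr - 1)
    c1 = np.minimum(c0 + 1, gc - 1)
    fr = (ri - r0)[:, None]
    fc = (ci - c0)[None, :]

    v = img
    m00 = luts[r0[:, None], c0[None, :], v]
    m01 = luts[r0[:, None], c1[None, :], v]
    m10 = luts[r1[:, None], c0[None, :], v]
    m11 = luts[r1[:, None], c1[None, :], v]
    out = (
        (1 - fr) * ((1 - fc) * m00 + fc * m01)
        + fr * ((1 - fc) * m10 + fc * m11)
    )
    return np.clip(np.rint(out), 0, levels - 1).astype(img.dtype)


def _he_lut_float(hist: np.ndarray, levels_out: int) -> np.ndarray:
    """Unrounded full-range CDF mapping (rounding happens after blending)."""
    cdf = np.cumsum(hist)
    total = cdf[-1]
    occupied = np.nonzero(hist)[0]
    cdf_min = cdf[occupied[0]] if occupied.size else 0.0
    if total <= cdf_min:
        return np.arange(hist.size, dtype=np.float64)
    return (cdf - cdf_min) / (total - cdf_min) * (levels_out - 1)


def enhance(img: np.ndarray, cfg: EnhanceConfig | None = None) -> np.ndarray:
    """Full enhancement chain: crop -> global HE -> CLAHE.

    Each stage is individually skippable via the config flags; cropping is
    skipped when the source does not exceed ``crop_to``.
    """
    if cfg is None:
        cfg = EnhanceConfig()
    img = _check_int_gray(img)
    if cfg.crop_to is not None:
        h, w = img.shape
        tw, th = min(cfg.crop_to[0], w), min(cfg.crop_to[1], h)
        if (tw, th) != (w, h):
            img = crop_center(img, (tw, th))
    if cfg.apply_he:
        img = hist_equalize(img)
    if cfg.apply_clahe:
        img = clahe(img, clip=cfg.clahe_clip, grid=cfg.clahe_grid)
    return img
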