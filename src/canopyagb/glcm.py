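"""Gray-level co-occurrence matrices and the eight Haralick-style statistics.

The texture quantities are the classic GLCM summaries: mean (Mea), variance
(Var), homogeneity (Hom), contrast (Con), dissimilarity (Dis), entropy (Ent,
log base 2), second moment / energy (Sec) and correlation (Cor).  They are
computed per channel, per direction and per moving window on gray-level
quantized imagery, then aggregated to plot level as the ROI mean of the
per-pixel texture grids.

Feature naming follows the channel-prefix scheme ``R-GDS30-Con`` /
``R-S2-Ent``: channel, source tag (ground-resolution level or Gabor scale),
statistic.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Sequence, Tuple

import numpy as np

from ._window_stats import STAT_ORDER, window_texture_stats
from .raster import Raster, ROIBox, quantize, resample_nearest

__all__ = [
    "GLCMConfig",
    "GLCM",
    "STATISTICS",
    "CHANNELS",
    "DIRECTION_OFFSETS",
    "compute_glcm",
    "glcm_features",
    "texture_image",
    "texture_image_reference",
    "plot_glcm_features",
    "field_glcm_features",
    "feature_name",
]

STATISTICS = STAT_ORDER
CHANNELS = ("R", "G", "B")

#: unit pixel offsets (row, col) per direction; 45/135 step toward the upper row
DIRECTION_OFFSETS = {0: (0, 1), 45: (-1, 1), 90: (-1, 0), 135: (-1, -1)}


@dataclass(frozen=True)
class GLCMConfig:
    """Windowed GLCM extraction settings.

    The default selection (45 deg, 5x5) is the single configuration the
    pipeline carries through to plot-level features; direction and window
    sweeps are exposed for the response analyses.
    """

    directions: Tuple[int, ...] = (0, 45, 90, 135)
    windows: Tuple[int, ...] = (3, 5, 7, 9)
    distance: int = 1
    levels: int = 32
    symmetric: bool = True
    selection_direction: int = 45
    selection_window: int = 5

    def __post_init__(self) -> None:
        for w in self.windows:
            if w < 3 or w % 2 == 0:
                raise ValueError(f"windows must be odd and >= 3, got {w}")
        for d in self.directions:
            if d not in DIRECTION_OFFSETS:
                raise ValueError(f"unsupported direction {d}")
        if self.distance < 1:
            raise ValueError("distance must be >= 1")
        if self.levels < 2:
            raise ValueError("levels must be >= 2")

    def offset(self, direction: int) -> Tuple[int, int]:
        dr, dc = DIRECTION_OFFSETS[direction]
        return (dr * self.distance, dc * self.distance)


@dataclass
class GLCM:
    """Normalised co-occurrence matrix with its generating offset."""

    p: np.ndarray
    offset: Tuple[int, int]
    symmetric: bool = True


def compute_glcm(
    gray: np.ndarray,
    offset: Tuple[int, int],
    levels: int,
    symmetric: bool = True,
) -> GLCM:
    """Co-occurrence probabilities of gray-level pairs at a fixed pixel offset.

    Every in-bounds ordered pixel pair (value i at x, value j at x + offset)
    is counted; in symmetric mode the reverse pair is counted as well.  The
    matrix is normalised to sum to one.
    """
    gray = np.asarray(gray)
    if gray.ndim != 2:
        raise ValueError("gray grid must be 2-D")
    if gray.min() < 0 or gray.max() >= levels:
        raise ValueError(f"gray values must lie in 0..{levels - 1}")
    dr, dc = offset
    H, W = gray.shape
    r0, r1 = max(0, -dr), H - max(0, dr)
    c0, c1 = max(0, -dc), W - max(0, dc)
    if r0 >= r1 or c0 >= c1:
        raise ValueError(f"grid {gray.shape} has no valid pixel pair for offset {offset}")
    i = gray[r0:r1, c0:c1].ravel()
    j = gray[r0 + dr : r1 + dr, c0 + dc : c1 + dc].ravel()
    codes = i.astype(np.int64) * levels + j
    counts = np.bincount(codes, minlength=levels * levels).astype(np.float64)
    p = counts.reshape(levels, levels)
    if symmetric:
        p = p + p.T
    p /= p.sum()
    return GLCM(p=p, offset=(dr, dc), symmetric=symmetric)


def glcm_features(g: GLCM | np.ndarray) -> Dict[str, float]:
    """The eight statistics of a normalised GLCM.

    Mea = sum_ij i p(i,j); Var = sum (i-Mea)^2 p; Hom = sum p/(1+(i-j)^2);
    Con = sum (i-j)^2 p; Dis = sum |i-j| p; Ent = -sum p log2 p (0 log 0 = 0);
    Sec = sum p^2; Cor = sum (i-mu_i)(j-mu_j) p / (sigma_i sigma_j), defined
    as 1 for degenerate (zero-variance) matrices.
    """
    p = g.p if isinstance(g, GLCM) else np.asarray(g, dtype=np.float64)
    L = p.shape[0]
    idx = np.arange(L, dtype=np.float64)
    ii = idx[:, None] * np.ones((1, L))
    jj = np.ones((L, 1)) * idx[None, :]
    diff = ii - jj
    mu_i = float((ii * p).sum())
    mu_j = float((jj * p).sum())
    var_i = float(((ii - mu_i) ** 2 * p).sum())
    var_j = float(((jj - mu_j) ** 2 * p).sum())
    nz = p > 0
    ent = float(-(p[nz] * np.log2(p[nz])).sum())
    denom = np.sqrt(var_i * var_j)
    if denom > 1e-12:
        cor = float((((ii - mu_i) * (jj - mu_j)) * p).sum() / denom)
    else:
        cor = 1.0  # constant windows are perfectly self-similar
    return {
        "Mea": mu_i,
        "Var": var_i,
        "Hom": float((p / (1.0 + diff**2)).sum()),
        "Con": float((diff**2 * p).sum()),
        "Dis": float((np.abs(diff) * p).sum()),
        "Ent": ent,
        "Sec": float((p**2).sum()),
        "Cor": cor,
    }


def texture_image(
    gray: np.ndarray,
    cfg: GLCMConfig,
    direction: int,
    window: int,
) -> Dict[str, np.ndarray]:
    """Per-pixel texture grids: one full-size grid per statistic.

    Each pixel's value is the statistic of the symmetric GLCM computed over
    the centred ``window x window`` neighbourhood (reflect-padded at edges)
    with the direction's offset.
    """
    if window % 2 == 0:
        raise ValueError(f"window must be odd, got {window}")
    if direction not in DIRECTION_OFFSETS:
        raise ValueError(f"unsupported direction {direction}")
    stats = window_texture_stats(gray, window, cfg.offset(direction), cfg.levels)
    return {name: stats[k] for k, name in enumerate(STAT_ORDER)}


def texture_image_reference(
    gray: np.ndarray,
    cfg: GLCMConfig,
    direction: int,
    window: int,
) -> Dict[str, np.ndarray]:
    """Slow per-pixel oracle: one explicit GLCM per window.  Test use only."""
    gray = np.asarray(gray)
    H, W = gray.shape
    r = window // 2
    padded = np.pad(gray, r, mode="reflect")
    out = {name: np.empty((H, W)) for name in STAT_ORDER}
    offset = cfg.offset(direction)
    for y in range(H):
        for x in range(W):
            win = padded[y : y + window, x : x + window]
            feats = glcm_features(compute_glcm(win, offset, cfg.levels, cfg.symmetric))
            for name in STAT_ORDER:
                out[name][y, x] = feats[name]
    return out


def feature_name(channel: str, source: str, statistic: str) -> str:
    """Canonical column name, e.g. ``R-S2-Ent`` or ``G-GDS30-Dis``."""
    return f"{channel}-{source}-{statistic}"


def _roi_texture_means(
    quantized: np.ndarray,
    roi_slices: Tuple[slice, slice],
    cfg: GLCMConfig,
    direction: int,
    window: int,
) -> Dict[str, float]:
    """ROI means of the 8 texture grids, computed on the ROI sub-grid only.

    The window is reflect-padded at the ROI boundary so texture values never
    mix in pixels from neighbouring plots or bare paths.
    """
    sub = quantized[roi_slices]
    if sub.shape[0] < window or sub.shape[1] < window:
        raise ValueError(
            f"ROI of {sub.shape} pixels is smaller than the {window}x{window} window"
        )
    stats = window_texture_stats(sub, window, cfg.offset(direction), cfg.levels)
    return {name: float(stats[k].mean()) for k, name in enumerate(STAT_ORDER)}


def field_glcm_features(
    rgb: Raster,
    rois: Sequence[ROIBox],
    cfg: GLCMConfig | None = None,
    gds_levels: Sequence[float] = (1, 5, 10, 20, 30, 40, 50, 60),
) -> "Dict[str, Dict[str, float]]":
    """Plot-level GLCM texture features for every ROI at every GDS level.

    For each level the GDS1 raster is resampled (single hop, nearest
    neighbour), each channel quantized against its full-image range, and the
    windowed statistics of the configured (direction, window) selection are
    averaged over each ROI.  Returns ``{plot_id: {feature_name: value}}``.
    """
    from .raster import _roi_pixel_slice

    cfg = cfg or GLCMConfig()
    if rgb.n_channels != 3:
        raise ValueError(f"expected a 3-channel DN raster, got {rgb.n_channels} channels")
    out: Dict[str, Dict[str, float]] = {roi.plot_id: {} for roi in rois}
    for level in gds_levels:
        res = resample_nearest(rgb, float(level))
        src = f"GDS{level:g}"
        for ch_idx, ch in enumerate(CHANNELS):
            q = quantize(res.channel(ch_idx), cfg.levels)
            for roi in rois:
                try:
                    slices = _roi_pixel_slice(res, roi)
                    feats = _roi_texture_means(
                        q, slices, cfg, cfg.selection_direction, cfg.selection_window
                    )
                except ValueError as err:
                    raise ValueError(f"{src}: ROI {roi.plot_id}: {err}") from err
                for stat, value in feats.items():
                    out[roi.plot_id][feature_name(ch, src, stat)] = value
    return out


def plot_glcm_features(
    rgb: Raster,
    roi: ROIBox,
    cfg: GLCMConfig | None = None,
    gds_levels: Sequence[float] = (1, 5, 10, 20, 30, 40, 50, 60),
) -> Dict[str, float]:
    """GLCM texture vector for a single plot (see :func:`field_glcm_features`)."""
    return field_glcm_features(rgb, [roi], cfg, gds_levels)[roi.plot_id]
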