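"""Crop height model (CHM) from DSM differencing and per-plot height extraction.

The CHM of a growth period is the per-pixel difference between that period's
DSM and the bare-soil DSM, with negative differences (soil subsidence or
photogrammetric noise) clamped to zero by default.  Plot height is the ROI
mean of the CHM, reported in centimetres.
"""

from __future__ import annotations

from typing import Dict, Sequence

import numpy as np

from .raster import Raster, ROIBox, roi_mean

__all__ = [
    "compute_chm",
    "plot_height",
    "plot_heights",
    "relative_residual",
    "height_diagnostics",
]


def compute_chm(dsm_period: Raster, dsm_bare: Raster, clamp_negative: bool = True) -> Raster:
    """CHM = period DSM - bare-soil DSM (metres), NaN where either is nodata."""
    mismatch = dsm_period.geometry_mismatch(dsm_bare)
    if mismatch:
        raise ValueError("DSM geometry mismatch: " + "; ".join(mismatch))
    a = np.asarray(dsm_period.values, dtype=np.float64)
    b = np.asarray(dsm_bare.values, dtype=np.float64)
    heights = a - b
    if clamp_negative:
        heights = np.where(np.isnan(heights), np.nan, np.maximum(heights, 0.0))
    return Raster(heights, dsm_period.gds_cm, dsm_period.origin)


def plot_height(chm: Raster, roi: ROIBox) -> float:
    """ROI-mean crop height in centimetres."""
    return roi_mean(chm, roi) * 100.0


def plot_heights(chm: Raster, rois: Sequence[ROIBox]) -> Dict[str, float]:
    return {roi.plot_id: plot_height(chm, roi) for roi in rois}


def relative_residual(estimated, observed):
    """100 * |estimated - observed| / observed, elementwise (percent)."""
    est = np.asarray(estimated, dtype=np.float64)
    obs = np.asarray(observed, dtype=np.float64)
    if np.any(obs <= 0):
        raise ValueError("observed heights must be positive for relative residuals")
    return 100.0 * np.abs(est - obs) / obs


def height_diagnostics(estimated, observed) -> Dict[str, float]:
    """Recovery diagnostics over a vector of plots: residuals and RMSE (cm)."""
    est = np.asarray(estimated, dtype=np.float64)
    obs = np.asarray(observed, dtype=np.float64)
    resid_pct = relative_residual(est, obs)
    return {
        "rmse_cm": float(np.sqrt(np.mean((est - obs) ** 2))),
        "mean_residual_pct": float(resid_pct.mean()),
        "frac_under_20pct": float(np.mean(resid_pct < 20.0)),
        "n": int(est.size),
    }
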