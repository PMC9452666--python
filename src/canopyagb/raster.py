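"""Raster data model, ROI zonal extraction, resampling and DN statistics.

Conventions (documented once, used everywhere):

* World coordinates are metres.  ``origin`` is the world coordinate of the
  *centre* of pixel (0, 0); the row index increases southward, so pixel
  (r, c) sits at ``(origin_x + c*g, origin_y - r*g)`` with ``g`` the ground
  sampling distance in metres.
* Ground sampling distance (GDS) is stored in centimetres per pixel.
* DN (digital number) rasters are uint8 in 0..255; DSM/CHM/magnitude rasters
  are float and may carry NaN as nodata.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np

__all__ = [
    "Raster",
    "ROIBox",
    "resample_nearest",
    "extract_roi",
    "roi_mean",
    "quantize",
    "channel_stats",
]

#: tolerance (in pixels) for deciding whether a pixel centre falls inside a box
_EDGE_EPS = 1e-9


@dataclass
class Raster:
    """A georeferenced grid of DN or float values.

    Parameters
    ----------
    values
        ``(H, W)`` or ``(H, W, C)`` array.  uint8 for DN imagery, float for
        elevation/height/magnitude surfaces.
    gds_cm
        Ground sampling distance, centimetres per pixel.
    origin
        World ``(x, y)`` of the centre of pixel (0, 0), metres.
    nodata
        Optional sentinel for DN rasters; float rasters use NaN.
    """

    values: np.ndarray
    gds_cm: float
    origin: Tuple[float, float] = (0.0, 0.0)
    nodata: Optional[float] = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim not in (2, 3):
            raise ValueError("raster values must be 2-D or 3-D (H, W[, C])")
        if self.values.shape[0] < 1 or self.values.shape[1] < 1:
            raise ValueError("raster must have at least one row and column")
        if self.gds_cm <= 0:
            raise ValueError(f"gds_cm must be positive, got {self.gds_cm}")
        if self.values.dtype == np.uint8:
            pass  # bounded 0..255 by construction
        self.origin = (float(self.origin[0]), float(self.origin[1]))

    # -- geometry helpers -------------------------------------------------
    @property
    def shape(self) -> Tuple[int, ...]:
        return self.values.shape

    @property
    def height(self) -> int:
        return self.values.shape[0]

    @property
    def width(self) -> int:
        return self.values.shape[1]

    @property
    def n_channels(self) -> int:
        return 1 if self.values.ndim == 2 else self.values.shape[2]

    @property
    def gds_m(self) -> float:
        return self.gds_cm / 100.0

    def channel(self, index: int) -> np.ndarray:
        """2-D view of one channel."""
        if self.values.ndim == 2:
            if index != 0:
                raise IndexError(f"single-channel raster has no channel {index}")
            return self.values
        if not 0 <= index < self.values.shape[2]:
            raise IndexError(f"channel {index} out of range for {self.n_channels}-channel raster")
        return self.values[:, :, index]

    def same_geometry(self, other: "Raster") -> bool:
        return (
            self.values.shape[:2] == other.values.shape[:2]
            and np.isclose(self.gds_cm, other.gds_cm)
            and np.allclose(self.origin, other.origin)
        )

    def geometry_mismatch(self, other: "Raster") -> list[str]:
        """Names of geometry properties that differ (empty when compatible)."""
        bad = []
        if self.values.shape[:2] != other.values.shape[:2]:
            bad.append(f"shape {self.values.shape[:2]} != {other.values.shape[:2]}")
        if not np.isclose(self.gds_cm, other.gds_cm):
            bad.append(f"gds_cm {self.gds_cm} != {other.gds_cm}")
        if not np.allclose(self.origin, other.origin):
            bad.append(f"origin {self.origin} != {other.origin}")
        return bad


@dataclass(frozen=True)
class ROIBox:
    """Axis-aligned plot rectangle in world metres."""

    plot_id: str
    xmin: float
    ymin: float
    xmax: float
    ymax: float

    def __post_init__(self) -> None:
        if not (self.xmax > self.xmin and self.ymax > self.ymin):
            raise ValueError(
                f"ROI {self.plot_id}: requires xmax > xmin and ymax > ymin, "
                f"got ({self.xmin}, {self.ymin}, {self.xmax}, {self.ymax})"
            )

    @property
    def width(self) -> float:
        return self.xmax - self.xmin

    @property
    def height(self) -> float:
        return self.ymax - self.ymin


def resample_nearest(r: Raster, target_gds_cm: float) -> Raster:
    """Down-sample to a coarser GDS with the nearest-neighbour pixel method.

    Output pixel ``(dst_r, dst_c)`` copies the source pixel at index
    ``floor((dst + 0.5) * target_gds / source_gds)`` in each axis
    (centre-of-pixel convention).  Values are copied, never interpolated.
    """
    if target_gds_cm < r.gds_cm:
        raise ValueError(
            f"target GDS {target_gds_cm} cm is finer than source {r.gds_cm} cm; "
            "only coarsening is supported"
        )
    if np.isclose(target_gds_cm, r.gds_cm):
        return Raster(r.values.copy(), r.gds_cm, r.origin, r.nodata)
    ratio = target_gds_cm / r.gds_cm
    out_h = int(np.floor(r.height / ratio))
    out_w = int(np.floor(r.width / ratio))
    if out_h < 1 or out_w < 1:
        raise ValueError(
            f"resampling {r.height}x{r.width} to GDS {target_gds_cm} cm yields empty output"
        )
    rows = np.floor((np.arange(out_h) + 0.5) * ratio).astype(np.intp)
    cols = np.floor((np.arange(out_w) + 0.5) * ratio).astype(np.intp)
    rows = np.clip(rows, 0, r.height - 1)
    cols = np.clip(cols, 0, r.width - 1)
    vals = r.values[np.ix_(rows, cols)] if r.values.ndim == 2 else r.values[np.ix_(rows, cols)]
    # origin moves to the centre of the first selected source pixel
    new_origin = (
        r.origin[0] + cols[0] * r.gds_m,
        r.origin[1] - rows[0] * r.gds_m,
    )
    return Raster(vals.copy(), target_gds_cm, new_origin, r.nodata)


def _roi_pixel_slice(r: Raster, roi: ROIBox) -> Tuple[slice, slice]:
    """Row/col slices of pixel centres falling inside the box."""
    g = r.gds_m
    ox, oy = r.origin
    eps = _EDGE_EPS * g
    c0 = int(np.ceil((roi.xmin - ox) / g - _EDGE_EPS))
    c1 = int(np.floor((roi.xmax - ox) / g + _EDGE_EPS))
    r0 = int(np.ceil((oy - roi.ymax) / g - _EDGE_EPS))
    r1 = int(np.floor((oy - roi.ymin) / g + _EDGE_EPS))
    c0, c1 = max(c0, 0), min(c1, r.width - 1)
    r0, r1 = max(r0, 0), min(r1, r.height - 1)
    if c0 > c1 or r0 > r1:
        raise ValueError(f"ROI {roi.plot_id} does not overlap the raster extent")
    return slice(r0, r1 + 1), slice(c0, c1 + 1)


def extract_roi(r: Raster, roi: ROIBox) -> Raster:
    """Sub-raster covering all pixel centres inside the box."""
    rs, cs = _roi_pixel_slice(r, roi)
    new_origin = (r.origin[0] + cs.start * r.gds_m, r.origin[1] - rs.start * r.gds_m)
    return Raster(r.values[rs, cs].copy(), r.gds_cm, new_origin, r.nodata)


def _valid_mask(vals: np.ndarray, nodata: Optional[float]) -> np.ndarray:
    mask = np.ones(vals.shape, dtype=bool)
    if np.issubdtype(vals.dtype, np.floating):
        mask &= np.isfinite(vals)
    if nodata is not None:
        mask &= vals != nodata
    return mask


def roi_mean(r: Raster, roi: ROIBox, channel: int = 0) -> float:
    """Arithmetic mean of one channel over the ROI, skipping nodata pixels."""
    sub = extract_roi(r, roi)
    vals = sub.channel(channel)
    mask = _valid_mask(vals, r.nodata)
    if not mask.any():
        raise ValueError(f"ROI {roi.plot_id}: all pixels are nodata")
    return float(vals[mask].astype(np.float64).mean())


def quantize(channel: np.ndarray, levels: int = 32) -> np.ndarray:
    """Linear binning of the observed [min, max] range into ``levels`` bins.

    Constant input maps to level 0.  The mapping is monotone non-decreasing.
    Returns an int32 grid with values in ``0..levels-1``.
    """
    if levels < 2:
        raise ValueError(f"levels must be >= 2, got {levels}")
    vals = np.asarray(channel, dtype=np.float64)
    lo, hi = float(np.nanmin(vals)), float(np.nanmax(vals))
    if hi <= lo:
        return np.zeros(vals.shape, dtype=np.int32)
    q = np.floor((vals - lo) / (hi - lo) * levels).astype(np.int32)
    return np.clip(q, 0, levels - 1)


def quantize_range(channel: np.ndarray, levels: int, lo: float, hi: float) -> np.ndarray:
    """Quantize against an externally supplied range (e.g. the full image's)."""
    if levels < 2:
        raise ValueError(f"levels must be >= 2, got {levels}")
    if hi <= lo:
        return np.zeros(np.asarray(channel).shape, dtype=np.int32)
    vals = np.asarray(channel, dtype=np.float64)
    q = np.floor((vals - lo) / (hi - lo) * levels).astype(np.int32)
    return np.clip(q, 0, levels - 1)


def channel_stats(r: Raster, channel: int = 0) -> Tuple[float, float]:
    """Data range (max - min) and population variance of one channel's DN values."""
    vals = r.channel(channel)
    mask = _valid_mask(vals, r.nodata)
    if not mask.any():
        raise ValueError("empty raster: no valid pixels")
    v = vals[mask].astype(np.float64)
    data_range = float(v.max() - v.min())
    variance = float(v.var())  # population variance (ddof=0)
    return data_range, variance
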