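"""Gabor wavelet filter bank, magnitude images and plot-level texture features.

The bank follows the classic Gabor-wavelet family: for orientation theta and
scale index nu (S1..S5 -> nu = 0..4) the wave number is ``k = k_max / f**nu``
with defaults ``k_max = pi/2``, ``f = sqrt(2)`` and Gaussian envelope width
``sigma = 2*pi``.  The kernel is

    g(z) = (k^2/sigma^2) * exp(-k^2 |z|^2 / (2 sigma^2)) * (exp(i k.z) - mu)

where ``mu`` is the envelope-weighted mean of the carrier over the truncated
support (analytically ~ exp(-sigma^2/2)), so every kernel has exactly zero DC
response and magnitude images are invariant to constant illumination offsets.
Support is truncated where the envelope falls below 1e-3 of its peak.

Texture statistics on magnitude images reuse the windowed GLCM machinery:
each magnitude raster is rescaled to 0..255 over its own range, quantized and
summarised by the same eight statistics.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Sequence, Tuple

import numpy as np
from scipy.signal import fftconvolve

from .glcm import CHANNELS, GLCMConfig, feature_name, _roi_texture_means
from .raster import Raster, ROIBox, quantize

__all__ = [
    "GaborParams",
    "GaborKernel",
    "GaborBank",
    "build_bank",
    "magnitude_images",
    "plot_gabor_features",
    "field_gabor_features",
    "DEFAULT_ORIENTATIONS",
    "DEFAULT_SCALES",
]

DEFAULT_ORIENTATIONS = (0, 45, 90, 135)
DEFAULT_SCALES = (1, 2, 3, 4, 5)


@dataclass(frozen=True)
class GaborParams:
    k_max: float = np.pi / 2  # peak spatial frequency, radians/pixel
    f: float = np.sqrt(2.0)  # spacing factor between scales
    sigma: float = 2.0 * np.pi  # envelope width (radians)
    truncate: float = 1e-3  # envelope cut-off relative to peak

    def __post_init__(self) -> None:
        if self.k_max <= 0 or self.f <= 0 or self.sigma <= 0:
            raise ValueError("Gabor family parameters must be positive")


@dataclass
class GaborKernel:
    orientation: int  # degrees
    scale: int  # 1..5 -> tag S1..S5
    values: np.ndarray  # complex, odd-sized square support

    @property
    def tag(self) -> str:
        return f"S{self.scale}"


@dataclass
class GaborBank:
    kernels: List[GaborKernel]
    params: GaborParams

    def __len__(self) -> int:
        return len(self.kernels)

    def select(self, orientation: int | None = None, scale: int | None = None) -> List[GaborKernel]:
        out = self.kernels
        if orientation is not None:
            out = [k for k in out if k.orientation == orientation]
        if scale is not None:
            out = [k for k in out if k.scale == scale]
        return out


def _make_kernel(theta_deg: float, nu: int, params: GaborParams) -> np.ndarray:
    k = params.k_max / params.f**nu
    sigma = params.sigma
    # truncation radius where the Gaussian envelope reaches `truncate` of peak
    radius = int(np.ceil(sigma / k * np.sqrt(2.0 * np.log(1.0 / params.truncate))))
    ax = np.arange(-radius, radius + 1, dtype=np.float64)
    dx, dy = np.meshgrid(ax, ax)  # dy increases with row index (southward)
    theta = np.deg2rad(theta_deg)
    kx, ky = k * np.cos(theta), k * np.sin(theta)
    r2 = dx**2 + dy**2
    envelope = np.exp(-(k**2) * r2 / (2.0 * sigma**2))
    carrier = np.exp(1j * (kx * dx + ky * dy))
    # exact zero-DC compensation over the truncated discrete support
    mu = (envelope * carrier).sum() / envelope.sum()
    kernel = (k**2 / sigma**2) * envelope * (carrier - mu)
    return kernel


def build_bank(
    orientations: Sequence[int] = DEFAULT_ORIENTATIONS,
    scales: Sequence[int] = DEFAULT_SCALES,
    params: GaborParams | None = None,
) -> GaborBank:
    """Build the orientation x scale kernel bank (default 4 x 5 = 20 kernels)."""
    if not orientations or not scales:
        raise ValueError("orientations and scales must be non-empty")
    params = params or GaborParams()
    kernels = [
        GaborKernel(orientation=int(o), scale=int(s), values=_make_kernel(o, int(s) - 1, params))
        for o in orientations
        for s in scales
    ]
    return GaborBank(kernels=kernels, params=params)


def _convolve_magnitude(channel: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """|channel * kernel| with reflect boundary handling, same output size."""
    radius = kernel.shape[0] // 2
    padded = np.pad(channel.astype(np.float64), radius, mode="reflect")
    response = fftconvolve(padded, kernel, mode="valid")
    return np.abs(response)


def magnitude_images(
    rgb: Raster, bank: GaborBank
) -> List[Tuple[Tuple[str, int, str], Raster]]:
    """Convolve each RGB channel with each kernel; per-pixel complex modulus.

    Returns a list of ``((channel, orientation, scale_tag), Raster)`` pairs;
    with the default 4x5 bank and a 3-channel raster that is 60 magnitude
    rasters.
    """
    if rgb.n_channels != 3:
        raise ValueError(f"expected a 3-channel DN raster, got {rgb.n_channels} channels")
    out = []
    for ch_idx, ch in enumerate(CHANNELS):
        channel = rgb.channel(ch_idx)
        for kern in bank.kernels:
            mag = _convolve_magnitude(channel, kern.values)
            out.append(
                (
                    (ch, kern.orientation, kern.tag),
                    Raster(mag, rgb.gds_cm, rgb.origin),
                )
            )
    return out


def _rescale_dn(mag: np.ndarray) -> np.ndarray:
    """Linear rescale of a magnitude image to 0..255 over its own range.

    (Near-)constant images map to 0: a range at the numerical noise floor
    must not be stretched into spurious full-scale texture.
    """
    lo, hi = float(mag.min()), float(mag.max())
    if hi - lo <= 1e-9 * max(abs(hi), 1.0):
        return np.zeros_like(mag)
    return (mag - lo) / (hi - lo) * 255.0


def field_gabor_features(
    rgb: Raster,
    rois: Sequence[ROIBox],
    bank: GaborBank | None = None,
    glcm_cfg: GLCMConfig | None = None,
    orientation: int | None = 45,
) -> Dict[str, Dict[str, float]]:
    """Plot-level texture statistics of Gabor magnitude images.

    Each magnitude raster is rescaled to 0..255 over its own range, quantized,
    and summarised by the windowed GLCM statistics (the configured selection
    direction/window), averaged per ROI.  With ``orientation`` set (default
    45 deg) only that orientation's kernels are used and keys read like
    ``R-S2-Ent``; with ``orientation=None`` the full bank is used and keys
    carry an explicit direction tag (8 stats x 60 magnitude images = 480
    features per plot).
    """
    from .raster import _roi_pixel_slice

    bank = bank or build_bank()
    glcm_cfg = glcm_cfg or GLCMConfig()
    kernels = bank.select(orientation=orientation)
    if not kernels:
        raise ValueError(f"bank has no kernels at orientation {orientation}")
    out: Dict[str, Dict[str, float]] = {roi.plot_id: {} for roi in rois}
    for ch_idx, ch in enumerate(CHANNELS):
        channel = rgb.channel(ch_idx)
        for kern in kernels:
            mag = _convolve_magnitude(channel, kern.values)
            q = quantize(_rescale_dn(mag), glcm_cfg.levels)
            src = kern.tag if orientation is not None else f"{kern.tag}-D{kern.orientation}"
            for roi in rois:
                try:
                    slices = _roi_pixel_slice(
                        Raster(q, rgb.gds_cm, rgb.origin), roi
                    )
                    feats = _roi_texture_means(
                        q,
                        slices,
                        glcm_cfg,
                        glcm_cfg.selection_direction,
                        glcm_cfg.selection_window,
                    )
                except ValueError as err:
                    raise ValueError(f"{src}: ROI {roi.plot_id}: {err}") from err
                for stat, value in feats.items():
                    out[roi.plot_id][feature_name(ch, src, stat)] = value
    return out


def plot_gabor_features(
    rgb: Raster,
    roi: ROIBox,
    bank: GaborBank | None = None,
    glcm_cfg: GLCMConfig | None = None,
    orientation: int | None = 45,
) -> Dict[str, float]:
    """Gabor texture vector for a single plot (see :func:`field_gabor_features`)."""
    return field_gabor_features(rgb, [roi], bank, glcm_cfg, orientation)[roi.plot_id]
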