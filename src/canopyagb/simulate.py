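"""Synthetic potato field generator.

Renders per-period RGB orthomosaics, DSMs, plot ROIs and ground truth with the
statistical structure the downstream analysis assumes:

* 48 plots in 3 replicate blocks, 0.6 m crop-row spacing, ~32.5 m2 plots at a
  1 cm ground sampling distance by default;
* canopy drawn as row-aligned leaf-blob clusters over mulched soil — blob
  density follows a per-plot cover parameter, blob size a leaf-size parameter;
* rise-then-fall cohort dynamics over the three growth periods (tuber
  formation P1, tuber growth P2, starch storage P3) for cover, height and AGB;
* a documented generative AGB model
  ``agb = beta0 + beta1 * cover * mean_height * m_period + eps``;
* additive measurement noise on observed plot height, AGB and the DSMs.

The canopy is procedural, not photorealistic: what matters downstream is that
the imagery carries spatial-frequency structure (leaf edges, canopy/soil
boundaries, per-period colour shifts), and that the DSM encodes a height field
whose ROI mean matches the recorded truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import ndimage

from .raster import Raster, ROIBox

__all__ = [
    "FieldDesign",
    "SimParams",
    "GroundTruth",
    "PeriodScene",
    "FieldScene",
    "PERIODS",
    "generate_period_scene",
    "generate_bare_soil_dsm",
    "generate_field",
    "write_scene",
]

PERIODS = ("P1", "P2", "P3")

#: default treatment cycle: density gradients, nitrogen gradients, potassium
_DEFAULT_TREATMENTS = ("T1", "T2", "T3", "N0", "N1", "N2", "N3", "K1")

#: latent vigour (0..1) by treatment; drives cover and height differences
_TREATMENT_VIGOUR = {
    "T1": 0.45,
    "T2": 0.55,
    "T3": 0.65,
    "N0": 0.35,
    "N1": 0.50,
    "N2": 0.62,
    "N3": 0.70,
    "K1": 0.55,
}


@dataclass(frozen=True)
class FieldDesign:
    """Plot layout of the synthetic experiment.

    Defaults mirror the study design: 48 plots of ~32.5 m2 in three replicate
    blocks with 0.6 m row spacing, imaged at 1 cm/pixel.
    """

    n_plots: int = 48
    n_repeats: int = 3
    plot_width: float = 6.5  # m, east-west
    plot_length: float = 5.0  # m, north-south (crop rows run east-west)
    row_spacing: float = 0.6  # m
    treatments: Optional[Tuple[str, ...]] = None
    gds_cm: float = 1.0
    seed: int = 0
    path_width: float = 0.5  # m, bare paths between plots and field margin

    def __post_init__(self) -> None:
        if self.n_plots < 1 or self.n_repeats < 1:
            raise ValueError("n_plots and n_repeats must be positive")
        if self.n_plots % self.n_repeats != 0:
            raise ValueError(
                f"n_plots ({self.n_plots}) must divide evenly into "
                f"{self.n_repeats} repeats"
            )
        if self.plot_width <= 0 or self.plot_length <= 0:
            raise ValueError("plot dimensions must be positive")
        if self.row_spacing <= 0:
            raise ValueError("row_spacing must be positive")
        if self.gds_cm <= 0:
            raise ValueError("gds_cm must be positive")
        if self.treatments is not None and len(self.treatments) != self.n_plots:
            raise ValueError("treatments must list one label per plot")

    @property
    def plots_per_repeat(self) -> int:
        return self.n_plots // self.n_repeats

    def treatment_labels(self) -> Tuple[str, ...]:
        if self.treatments is not None:
            return self.treatments
        return tuple(_DEFAULT_TREATMENTS[i % len(_DEFAULT_TREATMENTS)] for i in range(self.n_plots))

    def repeat_labels(self) -> Tuple[int, ...]:
        """Repeat label (1..n_repeats) per plot, in contiguous blocks."""
        return tuple(i // self.plots_per_repeat + 1 for i in range(self.n_plots))


@dataclass(frozen=True)
class SimParams:
    """Generative-model and appearance constants (all configurable).

    Cohort parameters encode the rise-then-fall phenology: cover, plant height
    and the AGB period multiplier all peak in P2.
    """

    # cohort phenology: base canopy cover and plant height per period
    base_cover: Tuple[float, float, float] = (0.50, 0.95, 0.70)
    base_height_cm: Tuple[float, float, float] = (32.0, 52.0, 42.0)
    # AGB generative model: agb = beta0 + beta1 * cover * mean_height * m + eps
    agb_beta0: float = 150.0
    agb_beta1: float = 50.0
    agb_period_mult: Tuple[float, float, float] = (0.62, 1.00, 0.80)
    agb_sigma: float = 110.0  # kg/hm2 measurement + model noise
    # measurement noise
    height_obs_sigma_cm: float = 1.5  # ruler/plot-sampling error on truth height
    dsm_noise_m: float = 0.008  # per-pixel photogrammetric DSM noise
    dsm_smooth_noise_m: float = 0.005  # smooth per-flight DSM artifact amplitude
    # terrain
    terrain_amp_m: float = 0.05  # low-relief amplitude (max |elevation|)
    terrain_scale_m: float = 12.0  # correlation length of the relief
    # canopy appearance
    leaf_size_cm: float = 9.0  # blob diameter; potato leaves are wide
    soil_rgb: Tuple[float, float, float] = (120.0, 96.0, 72.0)
    canopy_rgb: Dict[str, Tuple[float, float, float]] = dc_field(
        default_factory=lambda: {
            "P1": (62.0, 112.0, 56.0),
            "P2": (48.0, 122.0, 50.0),
            "P3": (96.0, 116.0, 52.0),  # yellowing during starch storage
        }
    )
    soil_jitter: float = 5.0  # DN sd of per-pixel soil speckle (mulched, smooth)
    canopy_jitter: float = 14.0  # DN sd of per-pixel leaf-facet speckle
    illumination_amp: float = 0.05  # relative amplitude of smooth illumination field
    illumination_scale_m: float = 4.0


@dataclass(frozen=True)
class GroundTruth:
    """Per plot-period ground truth record."""

    plot_id: str
    repeat: int
    treatment: str
    period: str
    cover_fraction: float
    mean_height: float  # cm, areal (ROI-mean) canopy height
    agb: float  # kg/hm2

    def __post_init__(self) -> None:
        if not 0.0 <= self.cover_fraction <= 1.0:
            raise ValueError("cover_fraction must be in [0, 1]")
        if self.mean_height < 0 or self.agb < 0:
            raise ValueError("mean_height and agb must be non-negative")


@dataclass
class PeriodScene:
    rgb: Raster
    dsm: Raster


@dataclass
class FieldScene:
    """A complete simulated campaign: all periods plus the bare-soil flight."""

    periods: Dict[str, PeriodScene]
    bare_dsm: Raster
    rois: List[ROIBox]
    truth: pd.DataFrame  # columns: io.TRUTH_COLUMNS


# ---------------------------------------------------------------------------
# layout and RNG plumbing
# ---------------------------------------------------------------------------


def _rng(seed: int, *key: int) -> np.random.Generator:
    """Deterministic substream keyed on integers."""
    return np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, *key]))


def field_layout(design: FieldDesign) -> Tuple[List[ROIBox], Tuple[int, int]]:
    """Plot ROIs in world metres plus the field grid shape in pixels.

    Plots are arranged in replicate bands from north to south; each band holds
    one repeat in a 2-row grid (or a single row for small repeats).
    """
    per_rep = design.plots_per_repeat
    band_rows = 2 if per_rep >= 8 and per_rep % 2 == 0 else 1
    n_cols = int(np.ceil(per_rep / band_rows))
    pw, pl, path = design.plot_width, design.plot_length, design.path_width
    total_rows = design.n_repeats * band_rows
    field_w = n_cols * pw + (n_cols + 1) * path
    field_h = total_rows * pl + (total_rows + 1) * path
    g = design.gds_cm / 100.0
    W = int(round(field_w / g))
    H = int(round(field_h / g))
    rois = []
    for i in range(design.n_plots):
        rep_idx = i // per_rep
        within = i % per_rep
        grid_row = rep_idx * band_rows + within // n_cols
        grid_col = within % n_cols
        xmin = path + grid_col * (pw + path)
        top = path + grid_row * (pl + path)
        ymax = field_h - top
        # shrink by half a pixel so ROI boundaries fall between pixel centres
        rois.append(
            ROIBox(
                plot_id=f"s{i + 1:02d}",
                xmin=xmin + g / 2,
                ymin=ymax - pl + g / 2,
                xmax=xmin + pw - g / 2,
                ymax=ymax - g / 2,
            )
        )
    return rois, (H, W)


def _world_origin(design: FieldDesign, shape: Tuple[int, int]) -> Tuple[float, float]:
    g = design.gds_cm / 100.0
    H, _ = shape
    return (g / 2, H * g - g / 2)


def _geometry_raster(design: FieldDesign, shape: Tuple[int, int]) -> Raster:
    """Lightweight raster carrying only grid geometry (np.empty is not touched)."""
    return Raster(np.empty(shape, dtype=np.bool_), design.gds_cm, _world_origin(design, shape))


# ---------------------------------------------------------------------------
# surfaces
# ---------------------------------------------------------------------------


def _smooth_noise(rng: np.random.Generator, shape: Tuple[int, int], sigma_px: float) -> np.ndarray:
    """Zero-mean smooth field normalised to unit max |amplitude|.

    Generated on a coarse grid (filter sigma ~2 px) and bilinearly upsampled,
    so the cost is independent of the correlation length.
    """
    factor = max(1, int(sigma_px / 2.0))
    coarse_shape = (int(np.ceil(shape[0] / factor)) + 2, int(np.ceil(shape[1] / factor)) + 2)
    f = ndimage.gaussian_filter(
        rng.standard_normal(coarse_shape), sigma=sigma_px / factor, mode="reflect"
    )
    if factor > 1:
        f = ndimage.zoom(f, factor, order=1, grid_mode=True, mode="nearest")
    f = f[: shape[0], : shape[1]]
    peak = np.abs(f).max()
    return f / peak if peak > 0 else f


def _terrain(design: FieldDesign, seed: int, params: SimParams, shape: Tuple[int, int]) -> np.ndarray:
    if params.terrain_amp_m <= 0:
        return np.zeros(shape, dtype=np.float64)
    sigma_px = max(params.terrain_scale_m / (design.gds_cm / 100.0), 1.0)
    base = _smooth_noise(_rng(seed, 101), shape, sigma_px)
    return params.terrain_amp_m * base


def generate_bare_soil_dsm(
    design: FieldDesign, seed: Optional[int] = None, params: Optional[SimParams] = None
) -> Raster:
    """Smooth low-relief bare-soil elevation surface, metres.

    Grid geometry matches the period DSMs from the same design/seed.  With
    ``terrain_amp_m = 0`` the surface is exactly constant; otherwise the
    max-min relief is bounded by twice the amplitude parameter.
    """
    seed = design.seed if seed is None else seed
    params = params or SimParams()
    _, shape = field_layout(design)
    dsm = _terrain(design, seed, params, shape)
    if params.dsm_noise_m > 0:
        dsm = dsm + params.dsm_noise_m * _rng(seed, 102, 0).standard_normal(shape)
    if params.dsm_smooth_noise_m > 0:
        sigma_px = max(1.5 / (design.gds_cm / 100.0), 1.0)
        dsm = dsm + params.dsm_smooth_noise_m * _smooth_noise(_rng(seed, 103, 0), shape, sigma_px)
    return Raster(dsm.astype(np.float32), design.gds_cm, _world_origin(design, shape))


# ---------------------------------------------------------------------------
# canopy rendering
# ---------------------------------------------------------------------------


def _canopy_mask_and_profile(
    rng: np.random.Generator,
    plot_shape: Tuple[int, int],
    design: FieldDesign,
    params: SimParams,
    cover_param: float,
) -> Tuple[np.ndarray, np.ndarray]:
    """Boolean canopy mask and a 0..1 crown profile for one plot.

    Leaf blobs are disks of diameter ``leaf_size_cm`` seeded along crop rows;
    the number of seeds follows a Boolean-model intensity so the rendered green
    fraction tracks the cover parameter, and seed sets are nested in the cover
    parameter (a larger cover re-uses all seeds of a smaller one), which makes
    the rendered fraction monotone in the parameter.
    """
    h_px, w_px = plot_shape
    g_cm = design.gds_cm
    radius_px = max(params.leaf_size_cm / 2.0 / g_cm, 1.0)
    row_spacing_px = design.row_spacing * 100.0 / g_cm
    n_rows = max(int(np.floor(h_px / row_spacing_px)), 1)
    row_centres = (np.arange(n_rows) + 0.5) * row_spacing_px

    # Boolean model: coverage c needs intensity -ln(1-c) disks per disk-area
    c_max = 0.985
    disk_area = np.pi * radius_px**2
    n_max = int(np.ceil(-np.log1p(-c_max) * h_px * w_px / disk_area))
    # candidate seeds, generated once; row-aligned with lateral spread that
    # widens as the canopy closes
    rows = rng.integers(0, n_rows, size=n_max)
    xs = rng.uniform(0, w_px, size=n_max)
    lateral = rng.standard_normal(n_max)
    u_order = rng.random(n_max)  # thinning ranks -> nested seed sets
    c = float(np.clip(cover_param, 0.0, c_max))
    n_use = int(np.ceil(-np.log1p(-c) * h_px * w_px / disk_area)) if c > 0 else 0
    keep = np.argsort(u_order)[:n_use]
    spread = row_spacing_px * (0.18 + 0.45 * c)
    ys = row_centres[rows[keep]] + lateral[keep] * spread
    xs = xs[keep]
    seed_grid = np.zeros(plot_shape, dtype=bool)
    yi = np.clip(np.round(ys).astype(int), 0, h_px - 1)
    xi = np.clip(np.round(xs).astype(int), 0, w_px - 1)
    seed_grid[yi, xi] = True
    if not seed_grid.any():
        return np.zeros(plot_shape, dtype=bool), np.zeros(plot_shape, dtype=np.float64)
    dist = ndimage.distance_transform_edt(~seed_grid)
    mask = dist <= radius_px
    # crown profile: tall in blob interiors, falling toward canopy edges
    inside = ndimage.distance_transform_edt(mask)
    profile = np.clip(inside / radius_px, 0.0, 1.0)
    return mask, profile


def _plot_vigour(design: FieldDesign, seed: int, plot_index: int, treatment: str) -> float:
    base = _TREATMENT_VIGOUR.get(treatment, 0.5)
    jitter = _rng(seed, 7, plot_index).normal(0.0, 0.08)
    return float(np.clip(base + jitter, 0.15, 1.0))


def generate_period_scene(
    design: FieldDesign,
    period: str,
    seed: Optional[int] = None,
    params: Optional[SimParams] = None,
) -> Tuple[Raster, Raster, List[ROIBox], List[GroundTruth]]:
    """Render one growth period: RGB orthomosaic, DSM, ROIs and ground truth.

    Identical ``(design, period, seed)`` produce byte-identical outputs.
    """
    if period not in PERIODS:
        raise ValueError(f"unknown period {period!r}; expected one of {PERIODS}")
    seed = design.seed if seed is None else seed
    params = params or SimParams()
    p_idx = PERIODS.index(period)
    rois, shape = field_layout(design)
    H, W = shape
    origin = _world_origin(design, shape)
    g_cm = design.gds_cm

    # soil background with mild speckle and a smooth illumination field
    rng_soil = _rng(seed, 11, p_idx)
    soil = np.asarray(params.soil_rgb, dtype=np.float64)
    rgb = np.empty((H, W, 3), dtype=np.float64)
    rgb[:] = soil
    if params.soil_jitter > 0:
        rgb += rng_soil.normal(0.0, params.soil_jitter, size=(H, W, 1))
    heights = np.zeros((H, W), dtype=np.float64)  # metres

    from .raster import _roi_pixel_slice

    geom = _geometry_raster(design, shape)
    treatments = design.treatment_labels()
    repeats = design.repeat_labels()
    truth: List[GroundTruth] = []
    base_cover = params.base_cover[p_idx]
    base_height = params.base_height_cm[p_idx]
    canopy_col = np.asarray(params.canopy_rgb[period], dtype=np.float64)

    for i, roi in enumerate(rois):
        rs, cs = _roi_pixel_slice(geom, roi)
        plot_shape = (rs.stop - rs.start, cs.stop - cs.start)
        vig = _plot_vigour(design, seed, i, treatments[i])
        rng_truth = _rng(seed, 13, p_idx, i)
        cover_param = float(
            np.clip(base_cover * (0.60 + 0.60 * vig) + rng_truth.normal(0.0, 0.03), 0.05, 0.97)
        )
        plant_height_cm = max(base_height * (0.80 + 0.40 * vig) + rng_truth.normal(0.0, 1.5), 5.0)

        rng_canopy = _rng(seed, 17, p_idx, i)
        mask, profile = _canopy_mask_and_profile(rng_canopy, plot_shape, design, params, cover_param)
        cover_measured = float(mask.mean())

        # height field: crowns rise from 60% to 100% of the plant height
        h_field = np.where(mask, plant_height_cm / 100.0 * (0.6 + 0.4 * profile), 0.0)
        heights[rs, cs] = h_field
        mean_height_cm = float(h_field.mean() * 100.0)

        # canopy colour: vigour-scaled base green, facet speckle, crown shading
        shade = 0.8 + 0.3 * profile[mask]
        col = canopy_col[None, :] * (0.85 + 0.30 * vig) * shade[:, None]
        if params.canopy_jitter > 0:
            col = col + rng_canopy.normal(0.0, params.canopy_jitter, size=col.shape)
        block = rgb[rs, cs]
        block[mask] = col
        rgb[rs, cs] = block

        obs_height = mean_height_cm + rng_truth.normal(0.0, params.height_obs_sigma_cm)
        agb = (
            params.agb_beta0
            + params.agb_beta1
            * cover_measured
            * mean_height_cm
            * params.agb_period_mult[p_idx]
            + rng_truth.normal(0.0, params.agb_sigma)
        )
        truth.append(
            GroundTruth(
                plot_id=roi.plot_id,
                repeat=repeats[i],
                treatment=treatments[i],
                period=period,
                cover_fraction=cover_measured,
                mean_height=max(obs_height, 0.0),
                agb=max(agb, 0.0),
            )
        )

    if params.illumination_amp > 0:
        sigma_px = max(params.illumination_scale_m / (g_cm / 100.0), 1.0)
        illum = 1.0 + params.illumination_amp * _smooth_noise(_rng(seed, 19, p_idx), shape, sigma_px)
        rgb *= illum[:, :, None]
    rgb_u8 = np.clip(np.round(rgb), 0, 255).astype(np.uint8)

    dsm = _terrain(design, seed, params, shape) + heights
    if params.dsm_noise_m > 0:
        dsm = dsm + params.dsm_noise_m * _rng(seed, 102, 1 + p_idx).standard_normal(shape)
    if params.dsm_smooth_noise_m > 0:
        sigma_px = max(1.5 / (g_cm / 100.0), 1.0)
        dsm = dsm + params.dsm_smooth_noise_m * _smooth_noise(
            _rng(seed, 103, 1 + p_idx), shape, sigma_px
        )

    rgb_raster = Raster(rgb_u8, g_cm, origin)
    dsm_raster = Raster(dsm.astype(np.float32), g_cm, origin)
    return rgb_raster, dsm_raster, rois, truth


def truth_to_frame(truth: Sequence[GroundTruth]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "plot_id": [t.plot_id for t in truth],
            "repeat": [t.repeat for t in truth],
            "treatment": [t.treatment for t in truth],
            "period": [t.period for t in truth],
            "cover_fraction": [t.cover_fraction for t in truth],
            "height_cm": [t.mean_height for t in truth],
            "agb_kg_hm2": [t.agb for t in truth],
        }
    )


def generate_field(
    design: FieldDesign,
    seed: Optional[int] = None,
    params: Optional[SimParams] = None,
    periods: Sequence[str] = PERIODS,
) -> FieldScene:
    """Simulate the full campaign: every requested period plus the bare flight."""
    seed = design.seed if seed is None else seed
    scenes: Dict[str, PeriodScene] = {}
    frames = []
    rois: List[ROIBox] = []
    for period in periods:
        rgb, dsm, rois, truth = generate_period_scene(design, period, seed, params)
        scenes[period] = PeriodScene(rgb=rgb, dsm=dsm)
        frames.append(truth_to_frame(truth))
    bare = generate_bare_soil_dsm(design, seed, params)
    return FieldScene(
        periods=scenes,
        bare_dsm=bare,
        rois=rois,
        truth=pd.concat(frames, ignore_index=True),
    )


def write_scene(scene: FieldScene, out_dir) -> dict:
    """Write a FieldScene to disk; returns a manifest of files with checksums."""
    from pathlib import Path

    from . import io as cio

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    files = {}
    for period, ps in scene.periods.items():
        files[f"rgb_{period}"] = cio.write_raster(out / f"rgb_{period}.tif", ps.rgb)
        files[f"dsm_{period}"] = cio.write_raster(out / f"dsm_{period}.tif", ps.dsm)
    files["dsm_bare"] = cio.write_raster(out / "dsm_bare.tif", scene.bare_dsm)
    files["rois"] = cio.write_rois_geojson(out / "rois.geojson", scene.rois)
    files["truth"] = cio.write_truth_csv(out / "truth.csv", scene.truth)
    manifest = {
        "files": {
            key: {"path": str(p.name), "sha256": cio.file_checksum(p)} for key, p in files.items()
        },
        "n_periods": len(scene.periods),
        "n_rois": len(scene.rois),
        "n_truth_rows": int(len(scene.truth)),
    }
    import json

    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest
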