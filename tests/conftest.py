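"""Shared fixtures: small synthetic scenes and the desk-scale pipeline runs.

Expensive artefacts (field generation, full texture extraction, the seed
sweep) are session-scoped so every test file shares one computation.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import canopyagb as ca
from canopyagb.pipeline import (
    desk_scale_config,
    extract_feature_table,
    fusion_sweep_config,
    height_fusion_sweep,
    run_scenarios,
)


@pytest.fixture(scope="session")
def tiny_design() -> ca.FieldDesign:
    """48 plots with a 1.2 x 1.2 m footprint: full layout, cheap rendering."""
    return ca.FieldDesign(plot_width=1.2, plot_length=1.2, seed=11)


@pytest.fixture(scope="session")
def tiny_scene(tiny_design) -> ca.FieldScene:
    return ca.generate_field(tiny_design, seed=11)


@pytest.fixture(scope="session")
def desk_cfg():
    return desk_scale_config(seed=0)


@pytest.fixture(scope="session")
def desk_scene(desk_cfg) -> ca.FieldScene:
    return ca.generate_field(desk_cfg.design, desk_cfg.seed, desk_cfg.sim_params)


@pytest.fixture(scope="session")
def desk_table(desk_cfg, desk_scene) -> pd.DataFrame:
    return extract_feature_table(desk_scene, desk_cfg)


@pytest.fixture(scope="session")
def desk_results(desk_cfg, desk_table):
    results, report = run_scenarios(desk_cfg, table=desk_table)
    return results, report


@pytest.fixture(scope="session")
def fusion_sweep_results() -> pd.DataFrame:
    return height_fusion_sweep(fusion_sweep_config(seed=0), n_seeds=10)


@pytest.fixture(scope="session")
def fullscale_height_run():
    """CHM recovery at the full study plot size (32.5 m2, GDS 1 cm)."""
    design = ca.FieldDesign(seed=5)
    scene = ca.generate_field(design, seed=5)
    from canopyagb.pipeline import extract_heights

    est = extract_heights(scene)
    merged = scene.truth.merge(
        est.rename(columns={"height_cm": "height_est_cm"}), on=["plot_id", "period"]
    )
    return merged


def rgb_raster(values: np.ndarray, gds_cm: float = 1.0) -> ca.Raster:
    return ca.Raster(np.asarray(values, dtype=np.uint8), gds_cm)
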