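"""Feature-table assembly, correlation-based pruning and the repeat split.

A feature table is a tidy pandas DataFrame with one row per plot-period,
identifier columns (``plot_id``, ``period``, ``repeat``, ``treatment``), the
regression target ``agb_kg_hm2`` and named feature columns (texture keys such
as ``R-S2-Ent`` and/or ``height_cm``).

Redundant features are pruned with a re-implementation of the pairwise
correlation-elimination algorithm popularised by caret's ``findCorrelation``
(cutoff 0.99 by default): repeatedly take the currently most-correlated pair
above the cutoff and drop the member with the larger mean absolute
correlation against all remaining variables.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Sequence, Set, Tuple

import numpy as np
import pandas as pd

__all__ = [
    "ID_COLUMNS",
    "TARGET_COLUMN",
    "SplitSpec",
    "assemble",
    "feature_columns",
    "find_correlation",
    "prune_features",
    "split_by_repeat",
]

ID_COLUMNS = ("plot_id", "period", "repeat", "treatment")
TARGET_COLUMN = "agb_kg_hm2"


@dataclass(frozen=True)
class SplitSpec:
    """Which replicate blocks form the calibration and validation sets."""

    calibration_repeats: Tuple[int, ...] = (2, 3)
    validation_repeats: Tuple[int, ...] = (1,)

    def __post_init__(self) -> None:
        if set(self.calibration_repeats) & set(self.validation_repeats):
            raise ValueError("calibration and validation repeats must be disjoint")
        if not self.calibration_repeats or not self.validation_repeats:
            raise ValueError("both splits must list at least one repeat")


def assemble(
    texture_tables: Sequence[pd.DataFrame],
    heights: pd.DataFrame | None,
    truth: pd.DataFrame,
    include: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Join texture vectors, plot heights and ground truth into one table.

    Parameters
    ----------
    texture_tables
        DataFrames keyed by (plot_id, period) with feature columns.
    heights
        Optional DataFrame with columns plot_id, period, height_cm.
    truth
        Ground-truth table carrying plot_id, period, repeat, treatment and
        the AGB target.
    include
        Optional explicit list of feature columns to keep (order preserved);
        by default all assembled features are kept in sorted order.
    """
    table = truth.loc[:, [*ID_COLUMNS, TARGET_COLUMN]].copy()
    table["plot_id"] = table["plot_id"].astype(str)
    n_expected = len(table)
    for tex in texture_tables:
        tex = tex.copy()
        tex["plot_id"] = tex["plot_id"].astype(str)
        table = table.merge(tex, on=["plot_id", "period"], how="left", validate="one_to_one")
    if heights is not None:
        heights = heights.copy()
        heights["plot_id"] = heights["plot_id"].astype(str)
        table = table.merge(
            heights.loc[:, ["plot_id", "period", "height_cm"]],
            on=["plot_id", "period"],
            how="left",
            validate="one_to_one",
        )
    if len(table) != n_expected:
        raise ValueError("texture/height tables introduced duplicate plot-period keys")
    feats = feature_columns(table)
    missing = table[feats].isna().any()
    if missing.any():
        bad_cols = list(missing.index[missing])
        bad_rows = table.loc[table[bad_cols].isna().any(axis=1), ["plot_id", "period"]]
        raise ValueError(
            f"missing feature values for plot-periods {bad_rows.to_records(index=False).tolist()[:5]}"
            f" in columns {bad_cols[:5]}"
        )
    if include is not None:
        unknown = [c for c in include if c not in table.columns]
        if unknown:
            raise ValueError(f"unknown feature columns requested: {unknown[:5]}")
        feats = list(include)
    else:
        feats = sorted(feats)
    return table.loc[:, [*ID_COLUMNS, TARGET_COLUMN, *feats]]


def feature_columns(table: pd.DataFrame) -> List[str]:
    reserved = {*ID_COLUMNS, TARGET_COLUMN}
    return [c for c in table.columns if c not in reserved]


def find_correlation(corr: np.ndarray, cutoff: float = 0.99) -> List[int]:
    """Indices of variables to remove so no remaining pair exceeds ``cutoff``.

    Re-implements the caret-style elimination: while any absolute pairwise
    correlation among the remaining variables exceeds the cutoff, take the
    largest such pair and remove the member with the larger mean absolute
    correlation against all other remaining variables (ties: remove the lower
    column index).  Returns sorted removal indices.
    """
    corr = np.asarray(corr, dtype=np.float64)
    if corr.ndim != 2 or corr.shape[0] != corr.shape[1]:
        raise ValueError("correlation matrix must be square")
    if not np.allclose(corr, corr.T, atol=1e-8):
        raise ValueError("correlation matrix must be symmetric")
    if np.nanmax(np.abs(corr)) > 1.0 + 1e-8:
        raise ValueError("correlation entries must lie in [-1, 1]")
    n = corr.shape[0]
    if not np.allclose(np.diag(corr), 1.0, atol=1e-8):
        raise ValueError("correlation matrix must have a unit diagonal")
    a = np.abs(corr)
    np.fill_diagonal(a, 0.0)
    active = np.ones(n, dtype=bool)
    removed: Set[int] = set()
    while active.sum() >= 2:
        sub = np.where(active)[0]
        block = a[np.ix_(sub, sub)]
        flat = np.argmax(block)
        i_loc, j_loc = divmod(flat, block.shape[1])
        if block[i_loc, j_loc] <= cutoff:
            break
        i, j = int(sub[min(i_loc, j_loc)]), int(sub[max(i_loc, j_loc)])
        # mean absolute correlation of each member against the other remaining vars
        others_i = [k for k in sub if k != i]
        others_j = [k for k in sub if k != j]
        mean_i = a[i, others_i].mean()
        mean_j = a[j, others_j].mean()
        if mean_i > mean_j:
            drop = i
        elif mean_j > mean_i:
            drop = j
        else:
            drop = min(i, j)
        active[drop] = False
        removed.add(drop)
    return sorted(removed)


def prune_features(
    table: pd.DataFrame,
    candidate_columns: Sequence[str],
    cutoff: float = 0.99,
) -> List[str]:
    """Columns surviving correlation pruning, computed on the given rows.

    Pearson correlations are computed on z-scored columns; zero-variance
    columns are treated as perfectly redundant beyond the first.
    """
    cols = list(candidate_columns)
    if len(cols) < 2:
        return cols
    X = table.loc[:, cols].to_numpy(dtype=np.float64)
    sd = X.std(axis=0)
    constant = sd == 0
    # correlations among non-constant columns
    keep_mask = ~constant
    live = [c for c, k in zip(cols, keep_mask) if k]
    if len(live) >= 2:
        corr = np.corrcoef(table.loc[:, live].to_numpy(dtype=np.float64), rowvar=False)
        corr = np.clip(corr, -1.0, 1.0)
        np.fill_diagonal(corr, 1.0)
        removed = find_correlation(corr, cutoff)
        live = [c for k, c in enumerate(live) if k not in removed]
    return live


def split_by_repeat(
    table: pd.DataFrame, spec: SplitSpec = SplitSpec()
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Row-disjoint calibration/validation partition by replicate block."""
    repeats = set(int(r) for r in table["repeat"].unique())
    covered = set(spec.calibration_repeats) | set(spec.validation_repeats)
    if not repeats <= covered:
        raise ValueError(f"repeat labels {sorted(repeats - covered)} not covered by the split spec")
    cal = table[table["repeat"].isin(spec.calibration_repeats)].reset_index(drop=True)
    val = table[table["repeat"].isin(spec.validation_repeats)].reset_index(drop=True)
    if len(cal) == 0:
        raise ValueError("calibration set is empty after the repeat split")
    if len(val) == 0:
        raise ValueError("validation set is empty after the repeat split")
    return cal, val
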