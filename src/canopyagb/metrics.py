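"""Estimation-accuracy metrics: R2, RMSE, MAE and NRMSE.

NRMSE is the RMSE normalised by the mean of the observed values, as a
percentage.  R2 is 1 - SS_res/SS_tot on the evaluated split (the squared
Pearson correlation is also reported for comparison, since the two diverge
for biased predictions).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np

__all__ = ["Metrics", "compute_metrics", "stratified_nrmse"]


@dataclass(frozen=True)
class Metrics:
    r2: float
    rmse: float
    mae: float
    nrmse: float  # percent
    n: int
    r2_pearson: float = float("nan")

    def as_dict(self) -> dict:
        return {
            "r2": self.r2,
            "rmse": self.rmse,
            "mae": self.mae,
            "nrmse": self.nrmse,
            "n": self.n,
            "r2_pearson": self.r2_pearson,
        }


def _as_vectors(observed, predicted) -> Tuple[np.ndarray, np.ndarray]:
    obs = np.asarray(observed, dtype=np.float64).ravel()
    pred = np.asarray(predicted, dtype=np.float64).ravel()
    if obs.shape != pred.shape:
        raise ValueError(f"length mismatch: observed {obs.size} vs predicted {pred.size}")
    if obs.size < 2:
        raise ValueError("need at least two observations")
    return obs, pred


def compute_metrics(observed, predicted) -> Metrics:
    obs, pred = _as_vectors(observed, predicted)
    resid = pred - obs
    ss_res = float((resid**2).sum())
    ss_tot = float(((obs - obs.mean()) ** 2).sum())
    if ss_tot <= 0:
        raise ValueError("observed values have zero variance; R2 undefined")
    mean_obs = float(obs.mean())
    if mean_obs <= 0:
        raise ValueError("mean of observed values must be positive for NRMSE")
    rmse = float(np.sqrt(ss_res / obs.size))
    if pred.std() > 0:
        r_pearson = float(np.corrcoef(obs, pred)[0, 1])
        r2_pearson = r_pearson**2
    else:
        r2_pearson = 0.0
    return Metrics(
        r2=1.0 - ss_res / ss_tot,
        rmse=rmse,
        mae=float(np.abs(resid).mean()),
        nrmse=100.0 * rmse / mean_obs,
        n=int(obs.size),
        r2_pearson=r2_pearson,
    )


def stratified_nrmse(
    observed, predicted, threshold: float = 1000.0
) -> Tuple[Optional[float], Optional[float]]:
    """NRMSE computed separately below/above an AGB threshold (kg/hm2).

    Each stratum is normalised by its own mean; an empty or degenerate stratum
    is reported as None (undefined).
    """
    obs = np.asarray(observed, dtype=np.float64).ravel()
    pred = np.asarray(predicted, dtype=np.float64).ravel()
    if obs.shape != pred.shape:
        raise ValueError("length mismatch")
    out = []
    for mask in (obs <= threshold, obs > threshold):
        if mask.sum() < 2:
            out.append(None)
            continue
        o, p = obs[mask], pred[mask]
        rmse = float(np.sqrt(np.mean((p - o) ** 2)))
        mean_o = float(o.mean())
        out.append(100.0 * rmse / mean_o if mean_o > 0 else None)
    return out[0], out[1]
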