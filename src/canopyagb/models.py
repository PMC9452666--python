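"""Regression models: LSSVM, ELM and PLSR behind one fit/predict contract.

* LSSVM: least-squares support vector regression with an RBF kernel,
  K(x_i, x_j) = exp(-||x_i - x_j||^2 / sigma2).  Training solves the single
  linear system  [[0, 1^T], [1, K + I/gamma]] [b; alpha] = [0; y].
* ELM: a single hidden layer of random (seeded) uniform(-1, 1) weights with a
  sigmoid activation; output weights are the least-squares solution via the
  Moore-Penrose pseudo-inverse.
* PLSR: PLS1 on centred/scaled data (scikit-learn's NIPALS-based
  implementation drives the latent decomposition).

All models standardise features by calibration-set statistics (z-score) and
pick hyperparameters by k-fold cross-validated RMSE on the calibration set
only.  Predictions align features by column name when a DataFrame is given.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from sklearn.cross_decomposition import PLSRegression
from sklearn.model_selection import KFold

__all__ = [
    "ModelSpec",
    "FittedModel",
    "fit_lssvm",
    "fit_elm",
    "fit_plsr",
    "fit_model",
    "predict",
    "rbf_kernel",
    "DEFAULT_GAMMA_GRID",
    "DEFAULT_SIGMA2_GRID",
    "DEFAULT_NODE_GRID",
]

# hyperparameter search grids (the study reports none; standard log-spaced grids)
DEFAULT_GAMMA_GRID = tuple(10.0 ** np.arange(-2, 4))  # 1e-2 .. 1e3
DEFAULT_SIGMA2_GRID = tuple(10.0 ** np.arange(-1, 4))  # 1e-1 .. 1e3
DEFAULT_NODE_GRID = (20, 50, 100)
DEFAULT_MAX_COMPONENTS = 10


@dataclass
class ModelSpec:
    """Hyperparameter search configuration for one model kind."""

    kind: str = "LSSVM"  # LSSVM | ELM | PLSR
    gamma_grid: Tuple[float, ...] = DEFAULT_GAMMA_GRID
    sigma2_grid: Tuple[float, ...] = DEFAULT_SIGMA2_GRID
    node_grid: Tuple[int, ...] = DEFAULT_NODE_GRID
    max_components: int = DEFAULT_MAX_COMPONENTS
    cv_folds: int = 5
    seed: int = 0
    # fixed hyperparameters (skip the search when given)
    gamma: Optional[float] = None
    sigma2: Optional[float] = None
    n_nodes: Optional[int] = None
    n_components: Optional[int] = None

    def __post_init__(self) -> None:
        kind = self.kind.upper()
        if kind not in {"LSSVM", "ELM", "PLSR"}:
            raise ValueError(f"unknown model kind {self.kind!r}")
        self.kind = kind
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")


@dataclass
class FittedModel:
    """Frozen fitted state; prediction is deterministic given this state."""

    kind: str
    feature_names: List[str]
    x_mean: np.ndarray
    x_sd: np.ndarray
    state: Dict
    hyperparameters: Dict

    def to_json(self) -> str:
        def _enc(v):
            if isinstance(v, np.ndarray):
                return v.tolist()
            return v

        payload = {
            "kind": self.kind,
            "feature_names": self.feature_names,
            "x_mean": self.x_mean.tolist(),
            "x_sd": self.x_sd.tolist(),
            "hyperparameters": self.hyperparameters,
            "state": {k: _enc(v) for k, v in self.state.items()},
        }
        return json.dumps(payload)


# ---------------------------------------------------------------------------
# shared plumbing
# ---------------------------------------------------------------------------


def _coerce_xy(X, y) -> Tuple[np.ndarray, np.ndarray, List[str]]:
    if isinstance(X, pd.DataFrame):
        names = [str(c) for c in X.columns]
        Xv = X.to_numpy(dtype=np.float64)
    else:
        Xv = np.asarray(X, dtype=np.float64)
        if Xv.ndim == 1:
            Xv = Xv[:, None]
        names = [f"x{i}" for i in range(Xv.shape[1])]
    yv = np.asarray(y, dtype=np.float64).ravel()
    if Xv.shape[0] != yv.size:
        raise ValueError(f"X has {Xv.shape[0]} rows but y has {yv.size}")
    if Xv.shape[0] < 3:
        raise ValueError("need at least 3 calibration rows")
    if np.isnan(Xv).any() or np.isnan(yv).any():
        raise ValueError("missing values are not allowed")
    return Xv, yv, names


def _standardize_fit(X: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    mean = X.mean(axis=0)
    sd = X.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)  # constant columns pass through centred
    return mean, sd


def _apply_standardize(X: np.ndarray, mean: np.ndarray, sd: np.ndarray) -> np.ndarray:
    return (X - mean) / sd


def rbf_kernel(A: np.ndarray, B: np.ndarray, sigma2: float) -> np.ndarray:
    """K(a, b) = exp(-||a-b||^2 / sigma2)."""
    a2 = (A**2).sum(axis=1)[:, None]
    b2 = (B**2).sum(axis=1)[None, :]
    d2 = np.maximum(a2 + b2 - 2.0 * A @ B.T, 0.0)
    return np.exp(-d2 / sigma2)


def _cv_rmse(train_predict, X: np.ndarray, y: np.ndarray, folds: int, seed: int) -> float:
    """Cross-validated RMSE of a closure (Xtr, ytr, Xte) -> predictions."""
    n = X.shape[0]
    folds = min(folds, n)
    kf = KFold(n_splits=folds, shuffle=True, random_state=seed & 0x7FFFFFFF)
    sq = 0.0
    for tr, te in kf.split(X):
        pred = train_predict(X[tr], y[tr], X[te])
        sq += float(((pred - y[te]) ** 2).sum())
    return np.sqrt(sq / n)


# ---------------------------------------------------------------------------
# LSSVM
# ---------------------------------------------------------------------------


def _lssvm_solve(K: np.ndarray, y: np.ndarray, gamma: float) -> Tuple[np.ndarray, float]:
    n = K.shape[0]
    A = np.empty((n + 1, n + 1))
    A[0, 0] = 0.0
    A[0, 1:] = 1.0
    A[1:, 0] = 1.0
    A[1:, 1:] = K + np.eye(n) / gamma
    rhs = np.concatenate(([0.0], y))
    try:
        sol = np.linalg.solve(A, rhs)
    except np.linalg.LinAlgError as err:
        cond = np.linalg.cond(A)
        raise np.linalg.LinAlgError(
            f"singular LSSVM system (condition estimate {cond:.3e})"
        ) from err
    return sol[1:], float(sol[0])


def fit_lssvm(X, y, spec: ModelSpec | None = None) -> FittedModel:
    """Fit the RBF-kernel LSSVM; (gamma, sigma2) by grid-searched CV RMSE."""
    spec = spec or ModelSpec(kind="LSSVM")
    Xv, yv, names = _coerce_xy(X, y)
    mean, sd = _standardize_fit(Xv)
    Z = _apply_standardize(Xv, mean, sd)
    if yv.std() == 0:
        return FittedModel(
            kind="LSSVM",
            feature_names=names,
            x_mean=mean,
            x_sd=sd,
            state={"constant": float(yv[0])},
            hyperparameters={"degenerate": True},
        )
    if spec.gamma is not None and spec.sigma2 is not None:
        best = (float(spec.gamma), float(spec.sigma2))
    else:

        def make_tp(gamma, sigma2):
            def tp(Xtr, ytr, Xte):
                alpha, b = _lssvm_solve(rbf_kernel(Xtr, Xtr, sigma2), ytr, gamma)
                return rbf_kernel(Xte, Xtr, sigma2) @ alpha + b

            return tp

        scores = {}
        for gamma in spec.gamma_grid:
            for sigma2 in spec.sigma2_grid:
                scores[(gamma, sigma2)] = _cv_rmse(
                    make_tp(gamma, sigma2), Z, yv, spec.cv_folds, spec.seed
                )
        best = min(scores, key=lambda k: (scores[k], k))
    gamma, sigma2 = best
    alpha, b = _lssvm_solve(rbf_kernel(Z, Z, sigma2), yv, gamma)
    return FittedModel(
        kind="LSSVM",
        feature_names=names,
        x_mean=mean,
        x_sd=sd,
        state={"support": Z, "alpha": alpha, "bias": b},
        hyperparameters={"gamma": float(gamma), "sigma2": float(sigma2)},
    )


# ---------------------------------------------------------------------------
# ELM
# ---------------------------------------------------------------------------


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def _elm_weights(d: int, nodes: int, seed: int) -> Tuple[np.ndarray, np.ndarray]:
    rng = np.random.default_rng(np.random.SeedSequence([seed & 0x7FFFFFFF, 23]))
    # uniform(-1, 1) draw, scaled by 1/sqrt(d) so the pre-activation variance
    # stays O(1) however many features enter; unscaled weights drive the
    # sigmoid into saturation for wide feature tables
    W = rng.uniform(-1.0, 1.0, size=(d, nodes)) / np.sqrt(d)
    b = rng.uniform(-1.0, 1.0, size=nodes)
    return W, b


def fit_elm(X, y, spec: ModelSpec | None = None) -> FittedModel:
    """Fit the ELM; hidden-node count by grid-searched CV RMSE."""
    spec = spec or ModelSpec(kind="ELM")
    Xv, yv, names = _coerce_xy(X, y)
    mean, sd = _standardize_fit(Xv)
    Z = _apply_standardize(Xv, mean, sd)
    d = Z.shape[1]

    def train(Xtr, ytr, nodes):
        W, b = _elm_weights(d, nodes, spec.seed)
        H = _sigmoid(Xtr @ W + b)
        beta = np.linalg.pinv(H) @ ytr
        return W, b, beta

    if spec.n_nodes is not None:
        if spec.n_nodes < 1:
            raise ValueError("hidden-node count must be >= 1")
        best_nodes = int(spec.n_nodes)
    else:
        grid = [n for n in spec.node_grid if n >= 1]
        if not grid:
            raise ValueError("hidden-node grid is empty")
        scores = {}
        for nodes in grid:

            def tp(Xtr, ytr, Xte, nodes=nodes):
                W, b, beta = train(Xtr, ytr, nodes)
                return _sigmoid(Xte @ W + b) @ beta

            scores[nodes] = _cv_rmse(tp, Z, yv, spec.cv_folds, spec.seed)
        best_nodes = min(scores, key=lambda k: (scores[k], k))
    W, b, beta = train(Z, yv, best_nodes)
    return FittedModel(
        kind="ELM",
        feature_names=names,
        x_mean=mean,
        x_sd=sd,
        state={"W": W, "b": b, "beta": beta},
        hyperparameters={"n_nodes": int(best_nodes), "seed": int(spec.seed)},
    )


# ---------------------------------------------------------------------------
# PLSR
# ---------------------------------------------------------------------------


def _pls_fit(Z: np.ndarray, y: np.ndarray, k: int) -> PLSRegression:
    model = PLSRegression(n_components=k, scale=False)
    model.fit(Z, y)
    return model


def fit_plsr(X, y, spec: ModelSpec | None = None) -> FittedModel:
    """Fit PLS1 regression; component count by grid-searched CV RMSE."""
    spec = spec or ModelSpec(kind="PLSR")
    Xv, yv, names = _coerce_xy(X, y)
    mean, sd = _standardize_fit(Xv)
    Z = _apply_standardize(Xv, mean, sd)
    rank = int(np.linalg.matrix_rank(Z - Z.mean(axis=0)))
    cap = max(1, min(spec.max_components, rank, Z.shape[0] - 1, Z.shape[1]))
    if spec.n_components is not None:
        if spec.n_components < 1:
            raise ValueError("component count must be >= 1")
        k = spec.n_components
        if k > cap:
            import warnings

            warnings.warn(
                f"requested {k} PLS components exceeds usable rank {cap}; capping",
                stacklevel=2,
            )
            k = cap
    else:
        scores = {}
        for k in range(1, cap + 1):
            # guard: folds shrink the training rank
            def tp(Xtr, ytr, Xte, k=k):
                kk = max(1, min(k, Xtr.shape[0] - 1))
                return _pls_fit(Xtr, ytr, kk).predict(Xte).ravel()

            scores[k] = _cv_rmse(tp, Z, yv, spec.cv_folds, spec.seed)
        k = min(scores, key=lambda s: (scores[s], s))
    model = _pls_fit(Z, yv, k)
    return FittedModel(
        kind="PLSR",
        feature_names=names,
        x_mean=mean,
        x_sd=sd,
        state={
            "coef": model.coef_.reshape(-1),
            "x_offset": np.asarray(model._x_mean, dtype=np.float64),
            "y_offset": float(np.asarray(model.intercept_).ravel()[0]),
        },
        hyperparameters={"n_components": int(k)},
    )


# ---------------------------------------------------------------------------
# common entry points
# ---------------------------------------------------------------------------

_FITTERS = {"LSSVM": fit_lssvm, "ELM": fit_elm, "PLSR": fit_plsr}


def fit_model(X, y, spec: ModelSpec) -> FittedModel:
    return _FITTERS[spec.kind](X, y, spec)


def _align_features(model: FittedModel, X_new) -> np.ndarray:
    if isinstance(X_new, pd.DataFrame):
        cols = [str(c) for c in X_new.columns]
        missing = [c for c in model.feature_names if c not in cols]
        extra = [c for c in cols if c not in model.feature_names]
        if missing or extra:
            raise ValueError(
                f"feature schema mismatch: missing {missing[:5]}, unexpected {extra[:5]}"
            )
        return X_new.loc[:, model.feature_names].to_numpy(dtype=np.float64)
    Xv = np.asarray(X_new, dtype=np.float64)
    if Xv.ndim == 1:
        Xv = Xv[None, :] if Xv.size == len(model.feature_names) else Xv[:, None]
    if Xv.shape[1] != len(model.feature_names):
        raise ValueError(
            f"expected {len(model.feature_names)} features, got {Xv.shape[1]}"
        )
    return Xv


def predict(model: FittedModel, X_new) -> np.ndarray:
    """Apply stored standardisation and the model's prediction rule."""
    Xv = _align_features(model, X_new)
    Z = _apply_standardize(Xv, model.x_mean, model.x_sd)
    if model.kind == "LSSVM":
        if "constant" in model.state:
            return np.full(Z.shape[0], model.state["constant"])
        sigma2 = model.hyperparameters["sigma2"]
        return rbf_kernel(Z, model.state["support"], sigma2) @ model.state["alpha"] + model.state[
            "bias"
        ]
    if model.kind == "ELM":
        return _sigmoid(Z @ model.state["W"] + model.state["b"]) @ model.state["beta"]
    if model.kind == "PLSR":
        Zc = Z - model.state["x_offset"]
        return Zc @ model.state["coef"] + model.state["y_offset"]
    raise ValueError(f"unknown model kind {model.kind!r}")
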