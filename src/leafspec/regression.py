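"""Regression engines for trait calibration: PLSR and a relu MLP.

PLSR here is PLS1 (one trait at a time) via NIPALS deflation with
mean-centering and no unit-variance scaling of the predictors — spectral
bands share units, and modelling traits separately accommodates samples
missing some traits. Predictions are affine in the input spectrum, and at
``n_lv = rank(X_centered)`` coincide with ordinary least squares.

The "deep neural network" comparator is a single-hidden-layer relu MLP
with an L2 penalty, trained on standardized predictors and response; the
hyperparameter grid is hidden sizes {5, 10, 15, 20} x L2 {0.005, 0.01,
0.03}. Training is reproducible at a fixed seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.neural_network import MLPRegressor

__all__ = [
    "PLSRModel",
    "MLPModel",
    "fit_plsr",
    "predict_plsr",
    "fit_mlp",
    "predict_mlp",
    "save_model",
    "load_model",
]

_SCHEMA_VERSION = 1


def _check_xy(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if X.ndim != 2:
        raise ValueError("X must be 2-D (samples x wavelengths)")
    if y.shape[0] != X.shape[0]:
        raise ValueError(f"X has {X.shape[0]} rows but y has {y.shape[0]} values")
    if not np.all(np.isfinite(X)):
        raise ValueError("X contains non-finite values")
    if not np.all(np.isfinite(y)):
        raise ValueError("y contains non-finite values (drop missing-trait samples first)")
    return X, y


@dataclass
class PLSRModel:
    """Fitted PLS1 model for one trait.

    ``n_lv`` is the requested latent-variable count; ``n_components_used``
    may be smaller when NIPALS exhausts the rank of the centered predictor
    matrix (further components would be numerically null).
    """

    n_lv: int
    x_mean: np.ndarray
    y_mean: float
    weights: np.ndarray      # (p, k) NIPALS weight vectors, unit norm
    x_loadings: np.ndarray   # (p, k)
    y_loadings: np.ndarray   # (k,)
    coef: np.ndarray         # (p,) regression coefficients on centered X
    n_components_used: int = 0

    @property
    def n_features(self) -> int:
        return int(self.x_mean.size)

    @property
    def intercept(self) -> float:
        return float(self.y_mean - self.x_mean @ self.coef)


def fit_plsr(
    X: np.ndarray,
    y: np.ndarray,
    n_lv: int,
    sample_weight: np.ndarray | None = None,
) -> PLSRModel:
    """Fit PLS1 by NIPALS with mean-centering.

    ``sample_weight`` (nonnegative) makes integer-weighted fits exactly
    equivalent to physically replicating rows — the efficient form of
    extra-weighted spiking.
    """
    X, y = _check_xy(X, y)
    n, p = X.shape
    bound = min(n - 1, p)
    if not (1 <= n_lv <= bound):
        raise ValueError(f"n_lv={n_lv} outside [1, min(n-1, p)] = [1, {bound}]")
    if sample_weight is None:
        w = np.ones(n)
    else:
        w = np.asarray(sample_weight, dtype=float)
        if w.shape != (n,) or np.any(w < 0) or w.sum() <= 0:
            raise ValueError("sample_weight must be nonnegative with positive sum")
    wsum = w.sum()
    x_mean = (w @ X) / wsum
    y_mean = float(w @ y / wsum)
    Xc = X - x_mean
    yc = y - y_mean
    if float(w @ yc**2) <= 1e-24 * max(1.0, y_mean**2):
        raise ValueError("y has zero variance; latent construction undefined")

    # columns collected in lists and stacked once, so the fitted arrays are
    # bit-identical whatever n_lv was requested beyond the effective rank
    W_cols: list[np.ndarray] = []
    P_cols: list[np.ndarray] = []
    q_vals: list[float] = []
    x_scale0 = float(np.sqrt((w[:, None] * Xc**2).sum()))
    for _ in range(n_lv):
        v = Xc.T @ (w * yc)
        vnorm = float(np.linalg.norm(v))
        # rank exhausted: remaining covariance is numerical noise
        if vnorm <= 1e-12 * max(x_scale0, 1.0):
            break
        wk = v / vnorm
        t = Xc @ wk
        tt = float(w @ t**2)
        if tt <= 1e-24 * max(x_scale0, 1.0) ** 2:
            break
        pk = Xc.T @ (w * t) / tt
        qk = float((w * yc) @ t / tt)
        Xc = Xc - np.outer(t, pk)
        yc = yc - qk * t
        W_cols.append(wk)
        P_cols.append(pk)
        q_vals.append(qk)

    k_used = len(W_cols)
    if k_used == 0:
        raise ValueError("no informative latent variable could be extracted")
    Wk = np.column_stack(W_cols)
    Pk = np.column_stack(P_cols)
    qk_ = np.array(q_vals)
    # B = W (P'W)^-1 q : coefficients of the affine prediction map
    coef = Wk @ np.linalg.solve(Pk.T @ Wk, qk_)
    return PLSRModel(
        n_lv=n_lv,
        x_mean=x_mean,
        y_mean=y_mean,
        weights=Wk,
        x_loadings=Pk,
        y_loadings=qk_,
        coef=coef,
        n_components_used=k_used,
    )


def predict_plsr(model: PLSRModel, X: np.ndarray) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[None, :]
    if X.shape[1] != model.n_features:
        raise ValueError(
            f"X has {X.shape[1]} wavelengths but the model was trained on {model.n_features}"
        )
    return (X - model.x_mean) @ model.coef + model.y_mean


@dataclass
class MLPModel:
    """Single-hidden-layer relu regressor with standardization parameters."""

    hidden_size: int
    l2: float
    seed: int
    x_mean: np.ndarray
    x_scale: np.ndarray
    y_mean: float
    y_scale: float
    coefs: list[np.ndarray] = field(default_factory=list)      # [(p, h), (h, 1)]
    intercepts: list[np.ndarray] = field(default_factory=list)  # [(h,), (1,)]

    @property
    def n_features(self) -> int:
        return int(self.x_mean.size)


def fit_mlp(
    X: np.ndarray,
    y: np.ndarray,
    hidden_size: int,
    l2: float,
    seed: int,
    max_iter: int = 2000,
    tol: float = 1e-6,
) -> MLPModel:
    """Train the relu MLP on standardized inputs and response.

    Uses L-BFGS (deterministic at fixed seed); stops on loss-change
    tolerance ``tol`` or after ``max_iter`` iterations.
    """
    X, y = _check_xy(X, y)
    x_mean = X.mean(axis=0)
    x_scale = X.std(axis=0)
    x_scale[x_scale == 0] = 1.0
    y_mean = float(y.mean())
    y_scale = float(y.std()) or 1.0
    Xs = (X - x_mean) / x_scale
    ys = (y - y_mean) / y_scale
    reg = MLPRegressor(
        hidden_layer_sizes=(hidden_size,),
        activation="relu",
        alpha=l2,
        solver="lbfgs",
        max_iter=max_iter,
        tol=tol,
        random_state=int(seed) % (2**31),
    )
    reg.fit(Xs, ys)
    if not np.isfinite(reg.loss_):
        raise RuntimeError(f"non-finite training loss after {reg.n_iter_} iterations")
    return MLPModel(
        hidden_size=hidden_size,
        l2=l2,
        seed=int(seed),
        x_mean=x_mean,
        x_scale=x_scale,
        y_mean=y_mean,
        y_scale=y_scale,
        coefs=[np.array(c) for c in reg.coefs_],
        intercepts=[np.array(b).ravel() for b in reg.intercepts_],
    )


def predict_mlp(model: MLPModel, X: np.ndarray) -> np.ndarray:
    """Forward pass from the stored weights; predictions in original units."""
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[None, :]
    if X.shape[1] != model.n_features:
        raise ValueError(
            f"X has {X.shape[1]} wavelengths but the model was trained on {model.n_features}"
        )
    h = (X - model.x_mean) / model.x_scale
    h = np.maximum(h @ model.coefs[0] + model.intercepts[0], 0.0)
    out = (h @ model.coefs[1]).ravel() + model.intercepts[1]
    return out * model.y_scale + model.y_mean


def _to_jsonable(a):
    return np.asarray(a).tolist()


def save_model(model: PLSRModel | MLPModel, path: str | Path) -> None:
    """Persist a fitted model as self-describing JSON (versioned schema)."""
    if isinstance(model, PLSRModel):
        payload = {
            "schema": _SCHEMA_VERSION,
            "kind": "plsr",
            "n_lv": model.n_lv,
            "n_components_used": model.n_components_used,
            "x_mean": _to_jsonable(model.x_mean),
            "y_mean": model.y_mean,
            "weights": _to_jsonable(model.weights),
            "x_loadings": _to_jsonable(model.x_loadings),
            "y_loadings": _to_jsonable(model.y_loadings),
            "coef": _to_jsonable(model.coef),
        }
    elif isinstance(model, MLPModel):
        payload = {
            "schema": _SCHEMA_VERSION,
            "kind": "mlp",
            "hidden_size": model.hidden_size,
            "l2": model.l2,
            "seed": model.seed,
            "x_mean": _to_jsonable(model.x_mean),
            "x_scale": _to_jsonable(model.x_scale),
            "y_mean": model.y_mean,
            "y_scale": model.y_scale,
            "coefs": [_to_jsonable(c) for c in model.coefs],
            "intercepts": [_to_jsonable(b) for b in model.intercepts],
        }
    else:
        raise TypeError(f"cannot persist {type(model).__name__}")
    Path(path).write_text(json.dumps(payload))


def load_model(path: str | Path) -> PLSRModel | MLPModel:
    payload = json.loads(Path(path).read_text())
    if payload.get("schema") != _SCHEMA_VERSION:
        raise ValueError(f"unsupported model schema: {payload.get('schema')}")
    if payload["kind"] == "plsr":
        return PLSRModel(
            n_lv=payload["n_lv"],
            x_mean=np.array(payload["x_mean"]),
            y_mean=payload["y_mean"],
            weights=np.array(payload["weights"]),
            x_loadings=np.array(payload["x_loadings"]),
            y_loadings=np.array(payload["y_loadings"]),
            coef=np.array(payload["coef"]),
            n_components_used=payload["n_components_used"],
        )
    if payload["kind"] == "mlp":
        return MLPModel(
            hidden_size=payload["hidden_size"],
            l2=payload["l2"],
            seed=payload["seed"],
            x_mean=np.array(payload["x_mean"]),
            x_scale=np.array(payload["x_scale"]),
            y_mean=payload["y_mean"],
            y_scale=payload["y_scale"],
            coefs=[np.array(c) for c in payload["coefs"]],
            intercepts=[np.array(b) for b in payload["intercepts"]],
        )
    raise ValueError(f"unknown model kind: {payload['kind']!r}")
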