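"""Hyperparameter selection by 10-fold cross-validated RMSE.

For each grid point the out-of-fold predictions are pooled across all k
folds and RMSE_CV / R²_CV are computed once on the pooled vector (this is
the single-number RMSE_CV convention; it equals the square root of the
fold-size-weighted mean of per-fold MSEs). The chosen point attains the
minimum RMSE_CV, with ties broken toward the smallest model (fewest
latent variables; smallest hidden size, then smallest L2). The final
model is refit on the whole calibration set at the chosen point.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from . import regression
from .evaluation import r_squared, rmse
from .spectra import SpectralLibrary

__all__ = [
    "PLSR_DEFAULT_GRID",
    "MLP_DEFAULT_GRID",
    "FoldAssignment",
    "CVResult",
    "CalibrationModel",
    "assign_folds",
    "cross_validate",
    "calibrate",
]

#: Latent-variable grid: models with as many as 30 latent variables.
PLSR_DEFAULT_GRID: tuple[int, ...] = tuple(range(1, 31))
#: Hidden sizes {5, 10, 15, 20} x L2 penalties {0.005, 0.01, 0.03}.
MLP_DEFAULT_GRID: tuple[tuple[int, float], ...] = tuple(
    (h, l2) for h in (5, 10, 15, 20) for l2 in (0.005, 0.01, 0.03)
)


@dataclass(frozen=True)
class FoldAssignment:
    k: int
    fold_of: np.ndarray  # per-sample fold index in [0, k)
    seed: int

    @property
    def n(self) -> int:
        return int(self.fold_of.size)


def assign_folds(n: int, k: int, seed: int) -> FoldAssignment:
    """Random near-even partition: fold sizes differ by at most one."""
    if k < 2:
        raise ValueError(f"k must be at least 2, got {k}")
    if n < k:
        raise ValueError(f"cannot split {n} samples into {k} folds")
    perm = np.random.default_rng(seed).permutation(n)
    fold_of = np.empty(n, dtype=int)
    fold_of[perm] = np.arange(n) % k
    return FoldAssignment(k=k, fold_of=fold_of, seed=int(seed))


@dataclass
class CVResult:
    """Cross-validation table for one trait and method."""

    method: str                       # "plsr" | "mlp"
    trait: str
    grid: list                        # evaluated grid points, ordered smallest-first
    rmse_cv: np.ndarray
    r2_cv: np.ndarray
    chosen_index: int
    n: int
    k: int
    seed: int
    skipped: list = field(default_factory=list)  # grid points infeasible at this n

    @property
    def chosen(self):
        return self.grid[self.chosen_index]

    @property
    def chosen_rmse_cv(self) -> float:
        return float(self.rmse_cv[self.chosen_index])

    @property
    def chosen_r2_cv(self) -> float:
        return float(self.r2_cv[self.chosen_index])

    def to_frame(self) -> pd.DataFrame:
        if self.method == "plsr":
            params = pd.DataFrame({"n_lv": self.grid})
        else:
            params = pd.DataFrame(self.grid, columns=["hidden_size", "l2"])
        params["method"] = self.method.upper()
        params["trait"] = self.trait
        params["rmse_cv"] = self.rmse_cv
        params["r2_cv"] = self.r2_cv
        params["chosen"] = False
        params.loc[self.chosen_index, "chosen"] = True
        return params


def _sorted_grid(method: str, grid: Sequence) -> list:
    pts = list(grid)
    if len(set(map(tuple, pts)) if method == "mlp" else set(pts)) != len(pts):
        raise ValueError("grid points must be unique")
    if method == "plsr":
        return sorted(int(g) for g in pts)
    return sorted((int(h), float(l2)) for h, l2 in pts)


def _fit_predict(method: str, Xtr, ytr, Xte, point, seed: int) -> np.ndarray:
    if method == "plsr":
        model = regression.fit_plsr(Xtr, ytr, n_lv=point)
        return regression.predict_plsr(model, Xte)
    model = regression.fit_mlp(Xtr, ytr, hidden_size=point[0], l2=point[1], seed=seed)
    return regression.predict_mlp(model, Xte)


def cross_validate(
    lib: SpectralLibrary,
    trait: str,
    method: str,
    grid: Sequence | None = None,
    folds: FoldAssignment | None = None,
    k: int = 10,
    seed: int = 0,
) -> CVResult:
    """k-fold CV over a hyperparameter grid for one trait.

    Samples with the trait missing are excluded before folding; their
    spectra are untouched. All grid points share the fold assignment.
    """
    if method not in ("plsr", "mlp"):
        raise ValueError(f"unknown method {method!r}")
    if grid is None:
        grid = PLSR_DEFAULT_GRID if method == "plsr" else MLP_DEFAULT_GRID
    grid = _sorted_grid(method, grid)
    if not grid:
        raise ValueError("empty hyperparameter grid")

    sub = lib.with_trait(trait)
    n = len(sub)
    if folds is None:
        folds = assign_folds(n, k, seed)
    if folds.n != n:
        raise ValueError(
            f"fold assignment covers {folds.n} samples but {n} have trait {trait!r}"
        )
    X = sub.spectra_matrix()
    y = sub.trait_values(trait)

    train_masks = []
    for f in range(folds.k):
        test = folds.fold_of == f
        train = ~test
        if np.std(y[train]) == 0:
            raise ValueError(f"fold {f}: training responses for {trait!r} have zero variance")
        train_masks.append((train, test))

    min_train = min(int(tr.sum()) for tr, _ in train_masks)
    p = X.shape[1]
    feasible, skipped = [], []
    for g in grid:
        if method == "plsr" and g > min(min_train - 1, p):
            skipped.append(g)
        else:
            feasible.append(g)
    if not feasible:
        raise ValueError("no feasible grid point for this sample size")
    if skipped:
        warnings.warn(
            f"{trait}/{method}: skipped {len(skipped)} grid point(s) infeasible at "
            f"min fold-train size {min_train}",
            stacklevel=2,
        )

    rmses = np.empty(len(feasible))
    r2s = np.empty(len(feasible))
    for i, point in enumerate(feasible):
        pooled = np.empty(n)
        for f, (train, test) in enumerate(train_masks):
            pooled[test] = _fit_predict(
                method, X[train], y[train], X[test], point, seed=folds.seed + 1000 * f
            )
        rmses[i] = rmse(y, pooled)
        r2s[i] = r_squared(y, pooled)

    chosen = int(np.argmin(rmses))  # first minimum = smallest model (grid sorted)
    return CVResult(
        method=method,
        trait=trait,
        grid=feasible,
        rmse_cv=rmses,
        r2_cv=r2s,
        chosen_index=chosen,
        n=n,
        k=folds.k,
        seed=folds.seed,
        skipped=skipped,
    )


@dataclass
class CalibrationModel:
    """Full-data refit at the CV-chosen grid point, with provenance."""

    trait: str
    method: str
    model: regression.PLSRModel | regression.MLPModel
    cv: CVResult
    window_nm: float | None = None  # preprocessing provenance

    def predict(self, X: np.ndarray) -> np.ndarray:
        if self.method == "plsr":
            return regression.predict_plsr(self.model, X)
        return regression.predict_mlp(self.model, X)


def calibrate(
    lib: SpectralLibrary,
    trait: str,
    method: str,
    grid: Sequence | None = None,
    seed: int = 0,
    k: int = 10,
    window_nm: float | None = None,
) -> CalibrationModel:
    """Tune by k-fold RMSE_CV, then refit on the whole calibration set."""
    cv = cross_validate(lib, trait, method, grid=grid, k=k, seed=seed)
    sub = lib.with_trait(trait)
    X = sub.spectra_matrix()
    y = sub.trait_values(trait)
    if method == "plsr":
        model: regression.PLSRModel | regression.MLPModel = regression.fit_plsr(
            X, y, n_lv=cv.chosen
        )
    else:
        h, l2 = cv.chosen
        model = regression.fit_mlp(X, y, hidden_size=h, l2=l2, seed=seed)
    return CalibrationModel(trait=trait, method=method, model=model, cv=cv, window_nm=window_nm)
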