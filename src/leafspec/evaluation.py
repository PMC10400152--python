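"""Prediction-quality statistics and the PCA spectral diagnostic.

Conventions (fixed so downstream comparisons are unambiguous):

* R² is the coefficient of determination 1 - SSE/SST with SST about the
  observed mean — not squared Pearson correlation. On external test sets
  it can be negative; nothing is clipped.
* bias = mean(predicted - observed).
* RPD = sample SD of the observations (n-1 denominator) / RMSE; the
  standard chemometric ratio of performance to deviation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.decomposition import PCA

from .spectra import GridMismatchError, Spectrum

__all__ = [
    "EvaluationReport",
    "PCADiagnostic",
    "r_squared",
    "rmse",
    "bias",
    "rpd",
    "evaluate",
    "pca_project",
]


def _pair(obs, pred) -> tuple[np.ndarray, np.ndarray]:
    obs = np.asarray(obs, dtype=float).ravel()
    pred = np.asarray(pred, dtype=float).ravel()
    if obs.shape != pred.shape:
        raise ValueError(f"length mismatch: {obs.size} observed vs {pred.size} predicted")
    return obs, pred


def r_squared(obs, pred) -> float:
    obs, pred = _pair(obs, pred)
    if obs.size < 2:
        raise ValueError("R² needs at least two observations")
    sst = float(np.sum((obs - obs.mean()) ** 2))
    if sst == 0.0:
        raise ValueError("observed values have zero variance; R² undefined")
    sse = float(np.sum((pred - obs) ** 2))
    return 1.0 - sse / sst


def rmse(obs, pred) -> float:
    obs, pred = _pair(obs, pred)
    if obs.size < 1:
        raise ValueError("RMSE needs at least one observation")
    return float(np.sqrt(np.mean((pred - obs) ** 2)))


def bias(obs, pred) -> float:
    obs, pred = _pair(obs, pred)
    if obs.size < 1:
        raise ValueError("bias needs at least one observation")
    return float(np.mean(pred - obs))


def rpd(obs, pred) -> float:
    obs, pred = _pair(obs, pred)
    if obs.size < 2:
        raise ValueError("RPD needs at least two observations")
    e = rmse(obs, pred)
    if e == 0.0:
        raise ValueError("RMSE is zero; RPD undefined (perfect prediction)")
    return float(np.std(obs, ddof=1)) / e


@dataclass(frozen=True)
class EvaluationReport:
    """Per-trait prediction quality on one evaluation set."""

    trait: str
    n: int
    r2: float
    rmse: float
    bias: float
    rpd: float | None  # None when RMSE == 0 (perfect prediction)


def evaluate(trait: str, obs, pred) -> EvaluationReport:
    obs, pred = _pair(obs, pred)
    e = rmse(obs, pred)
    return EvaluationReport(
        trait=trait,
        n=int(obs.size),
        r2=r_squared(obs, pred),
        rmse=e,
        bias=bias(obs, pred),
        rpd=rpd(obs, pred) if e > 0 else None,
    )


@dataclass
class PCADiagnostic:
    """First two principal components of a set of spectra, for shift diagnosis."""

    scores: np.ndarray               # (n, 2)
    loadings: np.ndarray             # (2, p)
    explained_variance_ratio: np.ndarray  # (2,)
    labels: list[str]

    def group_centroid(self, label: str) -> np.ndarray:
        mask = np.array([l == label for l in self.labels])
        if not mask.any():
            raise KeyError(f"no samples labelled {label!r}")
        return self.scores[mask].mean(axis=0)


def pca_project(spectra: list[Spectrum], labels: list[str]) -> PCADiagnostic:
    """Mean-centered PCA of spectra with group labels.

    The projection mirrors the standard library-vs-external diagnostic:
    domain shift shows up as separated group centroids / inflated
    ellipses in PC1-PC2 space.
    """
    if len(spectra) < 3:
        raise ValueError("PCA diagnostic needs at least three spectra")
    if len(labels) != len(spectra):
        raise ValueError("one label per spectrum required")
    grid = spectra[0].grid
    if any(s.grid != grid for s in spectra[1:]):
        raise GridMismatchError("spectra are on heterogeneous grids")
    X = np.vstack([s.values for s in spectra])
    n_comp = min(2, X.shape[0] - 1, X.shape[1])
    pca = PCA(n_components=n_comp, svd_solver="full")
    scores = pca.fit_transform(X)
    if n_comp < 2:  # degenerate but keep the 2-column contract
        scores = np.hstack([scores, np.zeros((X.shape[0], 2 - n_comp))])
    return PCADiagnostic(
        scores=scores[:, :2],
        loadings=pca.components_[:2],
        explained_variance_ratio=pca.explained_variance_ratio_[:2],
        labels=list(labels),
    )
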