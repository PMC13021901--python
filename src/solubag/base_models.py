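"""The three weak learners behind one fit/predict contract.

* polynomial regression: ridge-penalized least squares on a graded-lex
  monomial expansion of the standardized features;
* gamma regression: gamma GLM with log link on the same expansion, fitted
  by iteratively reweighted least squares (IRLS);
* K-nearest-neighbors regression: unweighted K-average under Euclidean
  distance on standardized features.

Temperature (~313-345 K) and pressure (~95-250 bar) live on incomparable
scales, so every family z-scores the raw features with training means and
standard deviations before expansion or distance computation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np

Family = Literal["polynomial", "knn", "gamma"]

MAX_DEGREE = 6
IRLS_MAX_ITER = 100
IRLS_TOL = 1e-10


class RankDeficiencyError(np.linalg.LinAlgError):
    """Unpenalized design matrix is singular."""


class ConvergenceError(RuntimeError):
    """IRLS failed to converge; carries the last iterate."""

    def __init__(self, message: str, last_coefficients: np.ndarray):
        super().__init__(message)
        self.last_coefficients = last_coefficients


class NotFittedError(RuntimeError):
    pass


@dataclass(frozen=True)
class RegressorConfig:
    """Configuration of one base learner.

    Only the fields relevant to ``family`` are consulted: ``degree`` and
    ``regularization`` for polynomial/gamma, ``k_neighbors`` and
    ``distance_metric`` for KNN.
    """

    family: Family
    degree: int = 2
    k_neighbors: int = 3
    distance_metric: Literal["euclidean", "manhattan"] = "euclidean"
    regularization: float = 1e-8

    def __post_init__(self) -> None:
        if self.family not in ("polynomial", "knn", "gamma"):
            raise ValueError(f"unknown family {self.family!r}")
        if self.family in ("polynomial", "gamma") and not (
            1 <= self.degree <= MAX_DEGREE
        ):
            raise ValueError(f"degree must be in [1, {MAX_DEGREE}]")
        if self.family == "knn" and self.k_neighbors < 1:
            raise ValueError("k_neighbors must be >= 1")
        if self.regularization < 0:
            raise ValueError("regularization must be >= 0")

    def to_dict(self) -> dict:
        return {
            "family": self.family,
            "degree": self.degree,
            "k_neighbors": self.k_neighbors,
            "distance_metric": self.distance_metric,
            "regularization": self.regularization,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RegressorConfig":
        return cls(**d)


@dataclass
class FittedRegressor:
    """A fitted base learner plus the preprocessing state needed to predict."""

    config: RegressorConfig
    scaler_mean: np.ndarray
    scaler_scale: np.ndarray
    coefficients: np.ndarray | None = None      # polynomial / gamma
    term_descriptors: list[tuple[int, int]] | None = None
    training_points: np.ndarray | None = None   # knn: standardized features
    training_targets: np.ndarray | None = None
    dispersion: float | None = None             # gamma: Pearson estimate

    @property
    def family(self) -> Family:
        return self.config.family

    def _standardize(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, dtype=float) - self.scaler_mean) / self.scaler_scale

    def predict(self, X) -> np.ndarray:
        return predict(self, X)


# ---------------------------------------------------------------------------
# polynomial term expansion (shared by polynomial and gamma families)
# ---------------------------------------------------------------------------

def polynomial_exponents(degree: int, n_features: int = 2) -> list[tuple[int, ...]]:
    """Exponent tuples of all monomials with total degree <= ``degree``,
    in graded lexicographic order: (0,0), (1,0), (0,1), (2,0), (1,1), ...
    """
    if degree < 1:
        raise ValueError("degree must be >= 1")
    if n_features != 2:
        raise ValueError("expansion is defined for the (T, P) feature pair")
    exps: list[tuple[int, ...]] = []
    for total in range(degree + 1):
        for a in range(total, -1, -1):
            exps.append((a, total - a))
    return exps


def expand_polynomial_terms(X, degree: int) -> np.ndarray:
    """Evaluate all monomials T^a * P^b with a + b <= degree, intercept first.

    Accepts a single (T, P) pair or an (n, 2) array; returns the design row
    or matrix with columns in graded-lex order.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    exps = polynomial_exponents(degree)
    cols = [X[:, 0] ** a * X[:, 1] ** b for a, b in exps]
    M = np.column_stack(cols)
    return M


def _ridge_solve(M: np.ndarray, y: np.ndarray, penalty: float,
                 weights: np.ndarray | None = None) -> np.ndarray:
    """Solve the (weighted) ridge normal equations; the intercept column
    (assumed first) is never penalized."""
    if weights is None:
        MtM = M.T @ M
        Mty = M.T @ y
    else:
        MW = M * weights[:, None]
        MtM = MW.T @ M
        Mty = MW.T @ y
    if penalty > 0:
        reg = np.eye(M.shape[1]) * penalty
        reg[0, 0] = 0.0
        MtM = MtM + reg
    elif np.linalg.matrix_rank(MtM) < M.shape[1]:
        raise RankDeficiencyError(
            "design matrix is rank deficient and regularization is 0"
        )
    return np.linalg.solve(MtM, Mty)


def _fit_scaler(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mean = X.mean(axis=0)
    scale = X.std(axis=0, ddof=0)
    scale = np.where(scale == 0, 1.0, scale)  # constant column: pass through
    return mean, scale


def fit_polynomial(X, y, cfg: RegressorConfig) -> FittedRegressor:
    """Ridge-penalized polynomial least squares on standardized features.

    With ``regularization == 0`` and a full-rank expansion this is exactly
    ordinary least squares; a singular unpenalized system raises
    :class:`RankDeficiencyError`.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    mean, scale = _fit_scaler(X)
    Z = (X - mean) / scale
    M = expand_polynomial_terms(Z, cfg.degree)
    beta = _ridge_solve(M, y, cfg.regularization)
    return FittedRegressor(
        config=cfg,
        scaler_mean=mean,
        scaler_scale=scale,
        coefficients=beta,
        term_descriptors=polynomial_exponents(cfg.degree),
    )


def fit_gamma(X, y, cfg: RegressorConfig) -> FittedRegressor:
    """Gamma GLM with log link by IRLS on the standardized expansion.

    The gamma/log-link IRLS has unit working weights, so each iteration is
    a ridge least-squares solve against the working response
    ``eta + (y - mu) / mu``.  Iteration starts from the least-squares fit of
    ``log y`` and stops when the relative deviance change drops below
    ``1e-10`` (cap 100 iterations).  The dispersion is the Pearson
    chi-square statistic over the residual degrees of freedom.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.any(y <= 0):
        raise ValueError("gamma regression requires strictly positive targets")
    mean, scale = _fit_scaler(X)
    Z = (X - mean) / scale
    M = expand_polynomial_terms(Z, cfg.degree)

    beta = _ridge_solve(M, np.log(y), cfg.regularization)

    def deviance(mu: np.ndarray) -> float:
        return float(2.0 * np.sum(-np.log(y / mu) + (y - mu) / mu))

    dev = np.inf
    for _ in range(IRLS_MAX_ITER):
        eta = M @ beta
        mu = np.exp(np.clip(eta, -500, 500))
        z = eta + (y - mu) / mu
        beta = _ridge_solve(M, z, cfg.regularization)
        new_dev = deviance(np.exp(np.clip(M @ beta, -500, 500)))
        if np.isfinite(dev) and abs(dev - new_dev) <= IRLS_TOL * (abs(dev) + IRLS_TOL):
            dev = new_dev
            break
        dev = new_dev
    else:
        raise ConvergenceError(
            f"IRLS did not converge in {IRLS_MAX_ITER} iterations", beta
        )

    mu = np.exp(M @ beta)
    dof = max(len(y) - M.shape[1], 1)
    dispersion = float(np.sum(((y - mu) / mu) ** 2) / dof)
    return FittedRegressor(
        config=cfg,
        scaler_mean=mean,
        scaler_scale=scale,
        coefficients=beta,
        term_descriptors=polynomial_exponents(cfg.degree),
        dispersion=dispersion,
    )


def fit_knn(X, y, cfg: RegressorConfig) -> FittedRegressor:
    """Store the standardized training set; prediction is lazy."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if cfg.k_neighbors > len(y):
        raise ValueError(
            f"k_neighbors={cfg.k_neighbors} exceeds training size {len(y)}"
        )
    mean, scale = _fit_scaler(X)
    return FittedRegressor(
        config=cfg,
        scaler_mean=mean,
        scaler_scale=scale,
        training_points=(X - mean) / scale,
        training_targets=y.copy(),
    )


_FITTERS = {"polynomial": fit_polynomial, "gamma": fit_gamma, "knn": fit_knn}


def fit(X, y, cfg: RegressorConfig) -> FittedRegressor:
    """Uniform dispatch: fit any family from its config."""
    return _FITTERS[cfg.family](X, y, cfg)


def knn_distance(a, b, metric: str = "euclidean") -> float:
    """Pointwise distance between two equal-length feature vectors."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"dimension mismatch: {a.shape} vs {b.shape}")
    if metric == "euclidean":
        return float(np.sqrt(np.sum((a - b) ** 2)))
    if metric == "manhattan":
        return float(np.sum(np.abs(a - b)))
    raise ValueError(f"unknown metric {metric!r}")


def knn_predict(q, model: FittedRegressor, k: int | None = None) -> float:
    """Unweighted mean of the targets of the k nearest training points.

    ``q`` is a raw (T, P) pair; it is standardized with the model's scaler.
    Ties at the k-th distance break by training-set index (earlier row
    wins), which makes the prediction deterministic.
    """
    if model.training_points is None:
        raise NotFittedError("KNN model has no training points")
    k = model.config.k_neighbors if k is None else k
    n = len(model.training_targets)
    if not (1 <= k <= n):
        raise ValueError(f"k={k} out of range [1, {n}]")
    z = (np.asarray(q, dtype=float) - model.scaler_mean) / model.scaler_scale
    diffs = model.training_points - z
    if model.config.distance_metric == "manhattan":
        d = np.abs(diffs).sum(axis=1)
    else:
        d = np.sqrt((diffs ** 2).sum(axis=1))
    order = np.argsort(d, kind="stable")  # stable sort = index tie-break
    return float(model.training_targets[order[:k]].mean())


def predict(model: FittedRegressor, X) -> np.ndarray:
    """Family-dispatched prediction over feature rows."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if model.family in ("polynomial", "gamma"):
        if model.coefficients is None:
            raise NotFittedError("model has no coefficients")
        M = expand_polynomial_terms(model._standardize(X), model.config.degree)
        eta = M @ model.coefficients
        return np.exp(eta) if model.family == "gamma" else eta
    return np.array([knn_predict(row, model) for row in X])
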