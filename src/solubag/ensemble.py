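"""Bootstrap aggregation (bagging) over any base-learner family.

Each member is fitted on a with-replacement resample ("bag") of the
training rows; the ensemble prediction is the plain arithmetic mean of the
member predictions.  The ensemble seed spawns one child seed per bag
(``seed + bag index``), so a fitted ensemble is fully reproducible while
members stay mutually independent.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .base_models import ConvergenceError, FittedRegressor, RegressorConfig, fit

MAX_BAG_RETRIES = 5


@dataclass
class FittedEnsemble:
    base_config: RegressorConfig
    members: list[FittedRegressor]
    n_estimators: int
    bootstrap_fraction: float
    rng_seed: int

    def predict(self, X) -> np.ndarray:
        return predict_bagged(self, X)


def fit_bagged(
    X,
    y,
    base_config: RegressorConfig,
    n_estimators: int = 100,
    bootstrap_fraction: float = 1.0,
    seed: int = 0,
    bootstrap: bool = True,
) -> FittedEnsemble:
    """Fit ``n_estimators`` base models on seeded bootstrap bags.

    Bags have size ``round(bootstrap_fraction * n)`` and are drawn with
    replacement; ``bootstrap=False`` gives every member the identity bag
    (useful as the degenerate single-model case).  A bag on which the base
    fit fails (e.g. a singular unpenalized design) is redrawn, at most
    5 times, before the error propagates.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(y)
    if n < 3:
        raise ValueError("bagging requires at least 3 training rows")
    if not (1 <= n_estimators):
        raise ValueError("n_estimators must be >= 1")
    if not (0 < bootstrap_fraction <= 1):
        raise ValueError("bootstrap_fraction must be in (0, 1]")
    bag_size = max(int(round(bootstrap_fraction * n)), 1)

    members: list[FittedRegressor] = []
    for b in range(n_estimators):
        rng = np.random.default_rng(seed + b)
        for attempt in range(MAX_BAG_RETRIES + 1):
            idx = (
                rng.integers(0, n, size=bag_size)
                if bootstrap
                else np.arange(n)
            )
            try:
                members.append(fit(X[idx], y[idx], base_config))
                break
            except (np.linalg.LinAlgError, ValueError, ConvergenceError):
                if not bootstrap or attempt == MAX_BAG_RETRIES:
                    raise
    return FittedEnsemble(
        base_config=base_config,
        members=members,
        n_estimators=n_estimators,
        bootstrap_fraction=bootstrap_fraction,
        rng_seed=seed,
    )


def predict_bagged(ens: FittedEnsemble, X) -> np.ndarray:
    """Row-wise arithmetic mean of member predictions."""
    preds = np.stack([m.predict(X) for m in ens.members])
    return preds.mean(axis=0)
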