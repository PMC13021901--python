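"""Study orchestration: tuning, fitting, evaluation, CV, importance, surfaces.

``run_study`` reproduces the full comparison — for each output (CO2
density, solubility) and each base family (polynomial, KNN, gamma), tune
the bagged model's hyperparameters with the bat algorithm, refit on the
training data and report the four evaluation statistics.  By default the
model is fitted and evaluated on all records, which is the protocol that
reproduces the published tables most closely; ``holdout_fraction`` switches
to a shuffled train/test split.

``run_cv`` cross-validates an already-selected configuration (refit per
fold, no nested re-tuning).  ``feature_importance`` is permutation
importance normalized to shares; ``effect_curve`` / ``effect_surface``
export plot-ready one- and two-factor prediction grids.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .base_models import RegressorConfig
from .bat_optimizer import _make_folds, tune_model
from .dataset_io import SolubilityDataset, TARGET_NAMES
from .ensemble import FittedEnsemble, fit_bagged, predict_bagged
from .metrics import MetricsReport, aggregate_cv, compute_metrics

logger = logging.getLogger("solubag")

DEFAULT_SEED = 20260313
FAMILIES = ("polynomial", "knn", "gamma")
FAMILY_LABELS = {"polynomial": "BAG + PR", "knn": "BAG + KNN", "gamma": "BAG + GR"}
OUTPUT_ORDER = ("co2_density", "solubility")


@dataclass
class StudyRow:
    output: str
    family: str
    config: RegressorConfig
    n_estimators: int
    cv_objective: float
    metrics: MetricsReport
    ensemble: FittedEnsemble

    @property
    def label(self) -> str:
        return FAMILY_LABELS[self.family]


@dataclass
class StudyReport:
    rows: list[StudyRow]
    seed: int

    def row(self, output: str, family: str) -> StudyRow:
        for r in self.rows:
            if r.output == output and r.family == family:
                return r
        raise KeyError((output, family))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "output": r.output,
                "method": r.label,
                "r2": r.metrics.r2,
                "rmse": r.metrics.rmse,
                "aard_percent": r.metrics.aard_percent,
                "max_error": r.metrics.max_error,
            }
            for r in self.rows
        )


def _combo_seed(seed: int, output: str, family: str) -> int:
    offset = 1 + OUTPUT_ORDER.index(output) * len(FAMILIES) + FAMILIES.index(family)
    return (seed + 65537 * offset) % (2**31)


def fit_model(
    ds: SolubilityDataset,
    output: str,
    config: RegressorConfig,
    n_estimators: int,
    seed: int,
) -> FittedEnsemble:
    """Fit the bagged model for one output on all records."""
    sel = ds.with_target(output)
    return fit_bagged(sel.features, sel.targets, config, n_estimators, seed=seed)


def run_study(
    ds: SolubilityDataset,
    seed: int = DEFAULT_SEED,
    families: tuple[str, ...] = FAMILIES,
    outputs: tuple[str, ...] = OUTPUT_ORDER,
    holdout_fraction: float | None = None,
    n_bats: int | None = None,
    n_iters: int | None = None,
) -> StudyReport:
    """Tune, fit and evaluate every (output, family) combination.

    With ``holdout_fraction`` unset the tuned model is fitted on all
    records and evaluated on the same records; otherwise a seeded shuffle
    puts that fraction of rows aside for evaluation only.
    """
    for output in outputs:
        if output not in TARGET_NAMES:
            raise ValueError(f"unknown output {output!r}")
    tune_kwargs = {}
    if n_bats is not None:
        tune_kwargs["n_bats"] = n_bats
    if n_iters is not None:
        tune_kwargs["n_iters"] = n_iters

    n = len(ds)
    rng = np.random.default_rng(seed)
    if holdout_fraction is not None:
        if not (0 < holdout_fraction < 1):
            raise ValueError("holdout_fraction must be in (0, 1)")
        perm = rng.permutation(n)
        n_test = max(2, int(round(holdout_fraction * n)))
        test_idx, train_idx = perm[:n_test], perm[n_test:]
    else:
        train_idx = test_idx = np.arange(n)

    rows = []
    for output in outputs:
        sel = ds.with_target(output)
        X, y = sel.features, sel.targets
        for family in families:
            combo_seed = _combo_seed(seed, output, family)
            t0 = time.perf_counter()
            config, n_estimators, cv_obj = tune_model(
                X[train_idx], y[train_idx], family, seed=combo_seed, **tune_kwargs
            )
            ens = fit_bagged(
                X[train_idx], y[train_idx], config, n_estimators, seed=combo_seed
            )
            report = compute_metrics(y[test_idx], predict_bagged(ens, X[test_idx]))
            logger.info(
                "study %s/%s: %s, n_estimators=%d, cv_rmse=%.4g, r2=%.4f (%.1fs)",
                output, family, config, n_estimators, cv_obj,
                report.r2, time.perf_counter() - t0,
            )
            rows.append(
                StudyRow(
                    output=output,
                    family=family,
                    config=config,
                    n_estimators=n_estimators,
                    cv_objective=cv_obj,
                    metrics=report,
                    ensemble=ens,
                )
            )
    return StudyReport(rows=rows, seed=seed)


def run_cv(
    ds: SolubilityDataset,
    config: RegressorConfig,
    n_estimators: int,
    output: str,
    k_folds: int = 5,
    seed: int = DEFAULT_SEED,
) -> dict[str, tuple[float, float]]:
    """K-fold CV of a selected configuration: refit per fold, evaluate on
    the held-out fold, aggregate mean +/- sample SD per metric.

    Folds come from a seeded shuffle into near-equal parts; a fold with
    fewer than 2 test points is merged into the previous fold.
    """
    sel = ds.with_target(output)
    X, y = sel.features, sel.targets
    if not (2 <= k_folds <= len(y)):
        raise ValueError("need 2 <= k_folds <= n")
    folds = _make_folds(len(y), k_folds, seed=seed + 7919)
    reports = []
    for f, test_idx in enumerate(folds):
        train_idx = np.setdiff1d(np.arange(len(y)), test_idx)
        ens = fit_bagged(
            X[train_idx], y[train_idx], config, n_estimators,
            seed=(seed + 104729 + 1000 * f) % (2**31),
        )
        reports.append(
            compute_metrics(y[test_idx], predict_bagged(ens, X[test_idx]))
        )
    return aggregate_cv(reports)


def feature_importance(
    ens: FittedEnsemble,
    X,
    y,
    n_repeats: int = 20,
    seed: int = DEFAULT_SEED,
    feature_names: tuple[str, str] = ("temperature", "pressure"),
) -> dict[str, float]:
    """Permutation importance as shares summing to 1.

    For each feature, the increase in RMSE after shuffling that column
    (mean over ``n_repeats`` seeded shuffles); negative increases are
    floored at 0 before normalization.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    rng = np.random.default_rng(seed)
    base_rmse = float(np.sqrt(np.mean((y - predict_bagged(ens, X)) ** 2)))
    raw = {}
    for j, name in enumerate(feature_names):
        increases = []
        for _ in range(n_repeats):
            Xp = X.copy()
            Xp[:, j] = rng.permutation(Xp[:, j])
            rmse = float(np.sqrt(np.mean((y - predict_bagged(ens, Xp)) ** 2)))
            increases.append(rmse - base_rmse)
        raw[name] = max(float(np.mean(increases)), 0.0)
    total = sum(raw.values())
    if total == 0:
        return {name: 1.0 / len(raw) for name in raw}
    return {name: v / total for name, v in raw.items()}


def effect_curve(
    ens: FittedEnsemble,
    varying: str,
    fixed_value: float,
    grid,
    train_range: tuple[float, float] | None = None,
) -> pd.DataFrame:
    """Predictions along a 1-D grid of one input, the other held fixed.

    Returns a plot-ready frame with columns (varying value, prediction,
    extrapolated); points outside ``train_range`` are flagged, not refused.
    """
    if varying not in ("temperature", "pressure"):
        raise ValueError("varying must be 'temperature' or 'pressure'")
    grid = np.asarray(grid, dtype=float)
    if varying == "temperature":
        X = np.column_stack([grid, np.full_like(grid, fixed_value)])
    else:
        X = np.column_stack([np.full_like(grid, fixed_value), grid])
    preds = predict_bagged(ens, X)
    extrapolated = (
        (grid < train_range[0]) | (grid > train_range[1])
        if train_range is not None
        else np.zeros(len(grid), dtype=bool)
    )
    return pd.DataFrame(
        {varying: grid, "prediction": preds, "extrapolated": extrapolated}
    )


def effect_surface(ens: FittedEnsemble, t_grid, p_grid) -> pd.DataFrame:
    """Cartesian (T, P) grid evaluation as a long-format frame."""
    t_grid = np.asarray(t_grid, dtype=float)
    p_grid = np.asarray(p_grid, dtype=float)
    T, P = np.meshgrid(t_grid, p_grid, indexing="ij")
    X = np.column_stack([T.ravel(), P.ravel()])
    return pd.DataFrame(
        {
            "temperature": X[:, 0],
            "pressure": X[:, 1],
            "prediction": predict_bagged(ens, X),
        }
    )
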