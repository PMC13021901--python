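"""Evaluation statistics for solubility-correlation models.

Four statistics per model/output pair — R2, RMSE, AARD% and maximum
absolute error — plus mean +/- SD aggregation over cross-validation folds.
AARD% (average absolute relative deviation, in percent) is the
field-standard error measure for supercritical solubility correlations;
it requires strictly positive observed values.
"""

from __future__ import annotations

from dataclasses import dataclass
from statistics import mean, stdev
from typing import Sequence

import numpy as np

METRIC_FIELDS = ("r2", "rmse", "aard_percent", "max_error")


@dataclass(frozen=True)
class MetricsReport:
    r2: float
    rmse: float
    aard_percent: float
    max_error: float
    n: int

    def to_dict(self) -> dict:
        return {
            "r2": self.r2,
            "rmse": self.rmse,
            "aard_percent": self.aard_percent,
            "max_error": self.max_error,
            "n": self.n,
        }


def compute_metrics(y_true, y_pred) -> MetricsReport:
    """R2 (sum-of-squares form, may be negative), RMSE, AARD%, max |error|.

    ``r2 = 1 - SS_res / SS_tot``; ``aard = (100/n) * sum(|y-yhat| / y)``.
    """
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have equal length")
    n = len(y_true)
    if n < 2:
        raise ValueError("metrics require at least 2 points")
    if np.any(y_true <= 0):
        raise ValueError("AARD%% requires strictly positive observed values")
    ss_tot = float(np.sum((y_true - y_true.mean()) ** 2))
    if ss_tot == 0:
        raise ValueError("R2 undefined: zero variance in y_true")
    resid = y_true - y_pred
    return MetricsReport(
        r2=1.0 - float(np.sum(resid ** 2)) / ss_tot,
        rmse=float(np.sqrt(np.mean(resid ** 2))),
        aard_percent=float(100.0 * np.mean(np.abs(resid) / y_true)),
        max_error=float(np.max(np.abs(resid))),
        n=n,
    )


def aggregate_cv(per_fold: Sequence[MetricsReport]) -> dict[str, tuple[float, float]]:
    """Per-metric arithmetic mean and sample SD (n-1) across folds."""
    if len(per_fold) < 2:
        raise ValueError("aggregation requires at least 2 folds")
    out = {}
    for name in METRIC_FIELDS:
        values = [getattr(r, name) for r in per_fold]
        out[name] = (mean(values), stdev(values))
    return out
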