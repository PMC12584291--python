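"""Original-scale performance metrics and best-model selection.

Models are scored on the scale the outcome is reported in (servings per EO,
or DGI points per day): RMSE, MAE and R² are computed from out-of-fold
predictions after back-transformation.  The best model per outcome is the one
with the lowest MAE — per-EO intakes contain outliers that would dominate a
squared-error criterion — with ties broken by lower RMSE, then higher R²,
then declaration order.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = ["MetricsReport", "compute_metrics", "select_best",
           "hurdle_allowed", "metrics_frame"]


@dataclass(frozen=True)
class MetricsReport:
    outcome: str
    model: str
    rmse: float
    mae: float
    r_squared: float | None
    n_predictions: int

    def __post_init__(self) -> None:
        if self.rmse < 0 or self.mae < 0:
            raise ValueError("rmse and mae are non-negative")
        if self.mae > self.rmse + 1e-12:
            raise ValueError("MAE cannot exceed RMSE")
        if self.r_squared is not None and self.r_squared > 1 + 1e-12:
            raise ValueError("r_squared cannot exceed 1")


def compute_metrics(predictions, actuals, outcome: str = "",
                    model: str = "") -> MetricsReport:
    """RMSE, MAE and R² (about the actuals' mean) on the original scale.

    With zero variance in the actuals R² is undefined and reported as None
    with a warning.
    """
    p = np.asarray(predictions, dtype=float)
    a = np.asarray(actuals, dtype=float)
    if p.shape != a.shape or p.ndim != 1:
        raise ValueError("predictions and actuals must be 1-D and equal length")
    if len(p) < 2:
        raise ValueError("at least two prediction/actual pairs are required")
    err = p - a
    rmse = float(np.sqrt(np.mean(err ** 2)))
    mae = float(np.mean(np.abs(err)))
    sst = float(np.sum((a - a.mean()) ** 2))
    if sst == 0:
        warnings.warn("actuals have zero variance; R² is undefined", stacklevel=2)
        r2 = None
    else:
        r2 = float(1.0 - np.sum(err ** 2) / sst)
    return MetricsReport(outcome=outcome, model=model, rmse=rmse, mae=mae,
                         r_squared=r2, n_predictions=len(p))


def select_best(reports: Sequence[MetricsReport]) -> MetricsReport:
    """Lowest-MAE report; ties: lower RMSE, then higher R², then input order."""
    if not reports:
        raise ValueError("no metrics reports to select from")

    def key(ir: tuple[int, MetricsReport]) -> tuple:
        i, r = ir
        r2 = -np.inf if r.r_squared is None else r.r_squared
        return (r.mae, r.rmse, -r2, i)

    return min(enumerate(reports), key=key)[1]


def hurdle_allowed(outcome: str) -> bool:
    """Hurdle models apply only to zero-inflated per-EO servings outcomes.

    Daily diet quality is a continuous daily score with no zeros, so hurdle
    families are invalid for it.
    """
    return not outcome.startswith("dgi")


def metrics_frame(reports: Sequence[MetricsReport]) -> pd.DataFrame:
    """Tabulate reports, one row per (outcome, model)."""
    return pd.DataFrame([{
        "outcome": r.outcome, "model": r.model, "rmse": r.rmse, "mae": r.mae,
        "r_squared": np.nan if r.r_squared is None else r.r_squared,
        "n_predictions": r.n_predictions,
    } for r in reports])
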