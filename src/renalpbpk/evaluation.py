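"""Predictive-performance metrics: fold errors, 2-fold / 1.25-fold windows, MAPE.

Model qualification for PBPK follows the conventional fold-error criteria: a
prediction is acceptable when pred/obs lies within [0.5, 2] (twofold) and
accurate when within [0.8, 1.25].  Precision and bias across a set of
predictions are summarised by the mean absolute prediction error,

    MAPE(%) = (1/n) * sum_i |pred_i - obs_i| * 100 / obs_i.

Both fold windows are inclusive at their boundaries and symmetric in log
space: swapping prediction and observation does not change the verdict.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = ["FoldError", "fold_error", "mape", "compare_models"]


@dataclass(frozen=True)
class FoldError:
    ratio: float
    within_2fold: bool
    within_125: bool


def fold_error(pred: float, obs: float) -> FoldError:
    """Prediction/observation ratio with inclusive 2-fold and 1.25-fold flags."""
    if obs <= 0:
        raise ValueError("observed value must be positive")
    if pred <= 0:
        raise ValueError("predicted value must be positive")
    r = pred / obs
    return FoldError(r, 0.5 <= r <= 2.0, 0.8 <= r <= 1.25)


def mape(pred: Sequence[float], obs: Sequence[float]) -> float:
    """Mean absolute prediction error in percent."""
    p = np.asarray(pred, dtype=float)
    o = np.asarray(obs, dtype=float)
    if p.shape != o.shape or p.ndim != 1 or len(p) < 1:
        raise ValueError("pred and obs must be equal-length 1-D sequences")
    if np.any(o <= 0):
        raise ValueError("observed values must be positive")
    return float(np.mean(np.abs(p - o) * 100.0 / o))


def compare_models(records: pd.DataFrame) -> pd.DataFrame:
    """Rank population models by predictive performance.

    ``records`` needs columns (model, predicted, observed); optional
    descriptive columns (drug, parameter, units) pass through untouched.
    Returns one row per model with MAPE, fraction within twofold and fraction
    within 0.8-1.25-fold, sorted by ascending MAPE.
    """
    for col in ("model", "predicted", "observed"):
        if col not in records.columns:
            raise ValueError(f"records lack required column {col!r}")
    if records["model"].nunique() < 2:
        raise ValueError("model comparison needs at least two model groups")
    rows = []
    for model, g in records.groupby("model"):
        flags = [fold_error(p, o) for p, o in zip(g["predicted"], g["observed"])]
        rows.append({
            "model": model,
            "n": len(g),
            "mape_pct": mape(g["predicted"], g["observed"]),
            "frac_within_2fold": float(np.mean([f.within_2fold for f in flags])),
            "frac_within_125": float(np.mean([f.within_125 for f in flags])),
        })
    return (
        pd.DataFrame(rows)
        .sort_values("mape_pct", kind="stable")
        .reset_index(drop=True)
    )
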