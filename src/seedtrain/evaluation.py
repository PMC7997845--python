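"""Prediction-accuracy metrics.

The central metric is the *relative prediction error*: the absolute
deviation between a predicted value and the measurement added later,
divided by that measurement, in percent.  Per updating step the errors
over the remaining prediction horizon are averaged; per seed train the
mean, minimum and maximum over all updating steps are reported.

Because offline cell-density measurements themselves carry an
intermediate-precision (within-lab reproducibility) error — 4.7%
coefficient of variation for the process emulated here — the relative
error is also expressed as a *precision-weighted prediction error*:
the ratio of the two, where values near 1 mean the model has reached
the irreducible measurement-uncertainty floor.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "DEFAULT_PRECISION_CV",
    "relative_prediction_error",
    "assess_prediction",
    "summarize",
    "precision_weighted_error",
    "PredictionAssessment",
]

#: Intermediate precision of viable-cell-density measurement [% CV].
DEFAULT_PRECISION_CV = 4.7


def relative_prediction_error(predicted, measured):
    """100 * |predicted - measured| / measured, elementwise.

    Undefined for non-positive measured values.
    """
    predicted = np.asarray(predicted, dtype=float)
    measured = np.asarray(measured, dtype=float)
    if np.any(measured <= 0):
        raise ValueError("relative prediction error undefined for measured <= 0")
    out = 100.0 * np.abs(predicted - measured) / measured
    return float(out) if out.ndim == 0 else out


def assess_prediction(
    predicted: pd.DataFrame, record, variables=("Xv", "Via", "cGlc", "cGln", "cLac", "cAmm")
) -> pd.DataFrame:
    """Join predictions with later measurements and attach relative errors.

    ``predicted`` is the tidy output of ``predict_future`` (scale_id,
    time_h, variable, predicted).  Rows without a matching measurement,
    or with a non-positive one, are dropped.
    """
    meas = record.measurements.rename(columns={"value": "measured"})
    df = predicted.merge(meas, on=["scale_id", "time_h", "variable"], how="inner")
    df = df[df["variable"].isin(variables)]
    df = df[np.isfinite(df["measured"]) & (df["measured"] > 0)].copy()
    df["rel_error_pct"] = 100.0 * np.abs(df["predicted"] - df["measured"]) / df["measured"]
    return df.reset_index(drop=True)


def summarize(step_errors) -> tuple[float, float, float]:
    """(mean, min, max) of per-updating-step errors over one seed train."""
    e = np.asarray(list(step_errors), dtype=float)
    if e.size == 0:
        raise ValueError("cannot summarize an empty sequence of step errors")
    return float(e.mean()), float(e.min()), float(e.max())


def precision_weighted_error(
    rel_error_percent: float, precision_cv_percent: float = DEFAULT_PRECISION_CV
) -> float:
    """Relative error divided by the intermediate-precision CV.

    Dimensionless; a value near 1 means the prediction error is of the
    order of the irreducible measurement uncertainty.
    """
    if precision_cv_percent <= 0:
        raise ValueError("precision CV must be positive")
    return float(rel_error_percent) / float(precision_cv_percent)


@dataclass(frozen=True)
class PredictionAssessment:
    """Per-point errors of one updating step plus per-step aggregates.

    ``per_point`` is the tidy frame from :func:`assess_prediction`;
    ``step_error`` maps each assessed variable to the mean relative
    error over the step's prediction-horizon points.
    """

    step_index: int
    per_point: pd.DataFrame
    step_error: dict[str, float] = field(default_factory=dict)

    @classmethod
    def from_points(cls, step_index: int, per_point: pd.DataFrame) -> "PredictionAssessment":
        step_error = (
            per_point.groupby("variable")["rel_error_pct"].mean().to_dict()
            if len(per_point)
            else {}
        )
        return cls(step_index=step_index, per_point=per_point, step_error=step_error)
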