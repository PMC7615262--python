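"""Evaluation metrics: brain-age delta, MAE and the age-delta correlation.

The age-delta correlation (ADC) is the correlation between the prediction
error δ = ŷ − y and chronological age y.  Regression dilution pulls
predictions toward the cohort mean, so an uncorrected regressor shows a
negative ADC: it overpredicts the young and underpredicts the old.

Undefined correlations (constant age or constant delta) raise
:class:`UndefinedCorrelationError` instead of silently returning NaN, so a
training controller can tell a collapsed model from a numeric bug.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Literal

import numpy as np
from scipy import stats

from .errors import InputError, UndefinedCorrelationError

AdcMethod = Literal["pearson", "spearman"]

__all__ = ["EvalReport", "delta", "mae", "adc"]


def _pair(y_hat, y):
    y_hat = np.atleast_1d(np.asarray(y_hat, dtype=float))
    y = np.atleast_1d(np.asarray(y, dtype=float))
    if y_hat.shape != y.shape:
        raise InputError(f"length mismatch: {y_hat.shape} vs {y.shape}")
    return y_hat, y


def delta(y_hat, y):
    """Brain-age delta δ = ŷ − y, elementwise (years)."""
    y_hat, y = _pair(y_hat, y)
    return y_hat - y


def mae(y_hat, y) -> float:
    """Mean absolute error in years."""
    y_hat, y = _pair(y_hat, y)
    if y.size == 0:
        raise InputError("mae of empty input")
    return float(np.mean(np.abs(y_hat - y)))


def adc(y_hat, y, method: AdcMethod = "pearson") -> float:
    """Age-delta correlation: corr(ŷ − y, y).

    Pearson is the product-moment correlation; Spearman is Pearson on the
    rank vectors (average ranks for ties), hence invariant to any strictly
    monotone transform of the delta.
    """
    y_hat, y = _pair(y_hat, y)
    if y.size < 2:
        raise InputError("adc requires at least 2 subjects")
    d = y_hat - y
    if np.ptp(y) == 0.0:
        raise UndefinedCorrelationError("chronological age is constant")
    if np.ptp(d) == 0.0:
        raise UndefinedCorrelationError("brain-age delta is constant")
    if method == "pearson":
        r = stats.pearsonr(d, y).statistic
    elif method == "spearman":
        r = stats.spearmanr(d, y).statistic
    else:
        raise InputError(f"unknown adc method {method!r}")
    return float(r)


@dataclass(frozen=True)
class EvalReport:
    """MAE and ADC of one prediction set."""

    mae: float
    adc: float
    adc_method: AdcMethod
    n: int

    @classmethod
    def from_predictions(cls, y_hat, y, adc_method: AdcMethod = "pearson") -> "EvalReport":
        y_hat, y = _pair(y_hat, y)
        return cls(
            mae=mae(y_hat, y),
            adc=adc(y_hat, y, adc_method),
            adc_method=adc_method,
            n=int(y.size),
        )

    def to_record(self) -> dict:
        return asdict(self)
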