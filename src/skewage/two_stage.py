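"""Post-hoc linear bias correction for brain-age predictions.

Two variants circulate in the literature:

* **Approach 2** (the default "two-stage" baseline): regress predicted age on
  chronological age on the *validation* set, ŷ = β₁·y + β₀, then invert that
  line on the test predictions, ŷ_corr = (ŷ − β₀)/β₁.  Only predictions are
  touched at application time, so it respects the predictive framework.
* **Approach 1**: regress the delta on age and subtract the fitted line,
  ŷ_corr = ŷ − (β₁·y + β₀).  This consumes test-set *labels* at application
  time and is therefore flagged; it is provided for completeness only.

Fitted on a set and applied to that same set, both yield a corrected delta
that is exactly uncorrelated with age (OLS residual orthogonality).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, asdict

import numpy as np
from scipy import stats

from .errors import DegenerateSlopeError, FitError, InputError

__all__ = [
    "CorrectionModel",
    "fit_correction_approach2",
    "apply_correction_approach2",
    "correct_approach1",
]

logger = logging.getLogger(__name__)

#: below this |slope| the inversion (ŷ − β₀)/β₁ blows up
MIN_ABS_SLOPE = 1e-6


@dataclass(frozen=True)
class CorrectionModel:
    """Slope/intercept of the validation-set regression of ŷ on y."""

    beta1: float
    beta0: float
    fitted_on: str = "validation"

    def to_record(self) -> dict:
        return asdict(self)


def _pair(a, b):
    a = np.atleast_1d(np.asarray(a, dtype=float))
    b = np.atleast_1d(np.asarray(b, dtype=float))
    if a.shape != b.shape:
        raise InputError(f"length mismatch: {a.shape} vs {b.shape}")
    return a, b


def fit_correction_approach2(y_hat_val, y_val, fitted_on: str = "validation") -> CorrectionModel:
    """OLS of predicted age on chronological age over the validation set."""
    y_hat_val, y_val = _pair(y_hat_val, y_val)
    if y_val.size < 3:
        raise FitError(f"need at least 3 subjects to fit the correction, got {y_val.size}")
    if np.ptp(y_val) == 0.0:
        raise FitError("chronological age is constant; slope undefined")
    res = stats.linregress(y_val, y_hat_val)
    if res.slope < 0:
        logger.warning(
            "correction slope beta1=%.4g is negative: predictions anti-correlated "
            "with age; corrected predictions will reverse order", res.slope,
        )
    return CorrectionModel(beta1=float(res.slope), beta0=float(res.intercept), fitted_on=fitted_on)


def apply_correction_approach2(model: CorrectionModel, y_hat):
    """Invert the fitted line on predictions: (ŷ − β₀)/β₁.  Never touches labels."""
    y_hat = np.atleast_1d(np.asarray(y_hat, dtype=float))
    if abs(model.beta1) < MIN_ABS_SLOPE:
        raise DegenerateSlopeError(
            f"|beta1|={abs(model.beta1):.3g} < {MIN_ABS_SLOPE}; correction would divide by ~0"
        )
    return (y_hat - model.beta0) / model.beta1


def correct_approach1(y_hat, y):
    """Label-using delta correction: ŷ − (β₁·y + β₀) with (β₁, β₀) from OLS of
    δ on y over the *same* data.

    Requires the true ages of the set being corrected, which leaks target
    labels in a predictive evaluation; callers should report results from
    this path as label-using.
    """
    y_hat, y = _pair(y_hat, y)
    if y.size < 3:
        raise FitError(f"need at least 3 subjects, got {y.size}")
    if np.ptp(y) == 0.0:
        raise FitError("chronological age is constant; slope undefined")
    d = y_hat - y
    if np.ptp(d) == 0.0:
        # perfect or uniformly shifted predictions: fitted line is the constant
        # delta itself, so the correction removes exactly that constant
        return y_hat - d
    res = stats.linregress(y, d)
    logger.info("approach-1 correction applied (uses target labels)")
    return y_hat - (res.slope * y + res.intercept)
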