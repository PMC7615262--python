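"""Age-dependent skew schedules λ(y) and the multiplicative step factor.

A skewed loss multiplies a symmetric base loss by

    s(r, y) = exp(sgn(r) · λ(y)),    r = y − ŷ,

so that for a subject of age y with λ(y) < 0 (young), overpredictions
(r < 0) are penalized by exp(−λ) > 1 while underpredictions are discounted,
and vice versa for λ(y) > 0 (old).  λ(y) is bounded in [−λ_max, +λ_max] and
non-decreasing in age; two linear shapes are provided:

* ``linear`` — λ interpolates linearly from −λ_max at the minimum age to
  +λ_max at the maximum age, crossing zero at the midpoint of the range.
* ``piecewise_median`` — two linear pieces meeting at λ(y_med) = 0, so that
  roughly half of a (possibly skewed) cohort gets a negative skew and half a
  positive one.  This is the default.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Literal

import numpy as np

from .errors import ConfigurationError, InputError

Mode = Literal["linear", "piecewise_median"]

__all__ = [
    "AgeStats",
    "LambdaSchedule",
    "StepParams",
    "make_schedule",
    "lambda_of_age",
    "step_factor",
    "step_factor_two_height",
    "with_lambda_max",
]


@dataclass(frozen=True)
class AgeStats:
    """Minimum, maximum and median age of the training cohort, in years."""

    y_min: float
    y_max: float
    y_med: float

    def __post_init__(self) -> None:
        for name in ("y_min", "y_max", "y_med"):
            v = getattr(self, name)
            if not math.isfinite(v):
                raise ConfigurationError(f"{name} must be finite, got {v!r}")
        if not self.y_min < self.y_max:
            raise ConfigurationError(
                f"degenerate age range: y_min={self.y_min} must be < y_max={self.y_max}"
            )
        if not (self.y_min <= self.y_med <= self.y_max):
            raise ConfigurationError(
                f"median age {self.y_med} outside range [{self.y_min}, {self.y_max}]"
            )

    @classmethod
    def from_ages(cls, ages) -> "AgeStats":
        ages = np.asarray(ages, dtype=float)
        if ages.size < 2:
            raise ConfigurationError("need at least two ages to compute age stats")
        return cls(float(ages.min()), float(ages.max()), float(np.median(ages)))


@dataclass(frozen=True)
class StepParams:
    """Two-height step function: factor λ0 for negative residuals, λ1 for
    nonnegative ones.  The one-parameter exponential form corresponds to
    λ0 = exp(−λ), λ1 = exp(+λ), which satisfies λ0·λ1 = 1 (inverse symmetry).
    """

    lambda0: float
    lambda1: float

    def __post_init__(self) -> None:
        if not (self.lambda0 > 0 and self.lambda1 > 0):
            raise ConfigurationError("step heights must be strictly positive")

    @classmethod
    def from_skew(cls, lam: float) -> "StepParams":
        return cls(math.exp(-lam), math.exp(lam))


@dataclass(frozen=True)
class LambdaSchedule:
    """Maps chronological age to a skew value in [−lambda_max, +lambda_max]."""

    stats: AgeStats
    lambda_max: float
    mode: Mode = "piecewise_median"

    def __post_init__(self) -> None:
        if not (math.isfinite(self.lambda_max) and self.lambda_max >= 0):
            raise ConfigurationError(
                f"lambda_max must be a finite nonnegative real, got {self.lambda_max!r}"
            )
        if self.mode not in ("linear", "piecewise_median"):
            raise ConfigurationError(f"unknown schedule mode {self.mode!r}")
        if self.mode == "piecewise_median":
            s = self.stats
            if s.y_med <= s.y_min or s.y_med >= s.y_max:
                raise ConfigurationError(
                    "piecewise_median mode requires y_min < y_med < y_max "
                    f"(got {s.y_min}, {s.y_med}, {s.y_max})"
                )

    # -- evaluation ---------------------------------------------------------

    def lambda_of_age(self, y):
        """Evaluate λ(y); ages outside [y_min, y_max] clamp to the boundary."""
        y = np.asarray(y, dtype=float)
        if not np.all(np.isfinite(y)):
            raise InputError("ages must be finite")
        s = self.stats
        yc = np.clip(y, s.y_min, s.y_max)
        if self.mode == "linear":
            g = (yc - s.y_min) / (s.y_max - s.y_min)
            lam = g * self.lambda_max + (1.0 - g) * (-self.lambda_max)
        else:
            lam = np.where(
                yc <= s.y_med,
                (1.0 - (yc - s.y_min) / (s.y_med - s.y_min)) * (-self.lambda_max),
                (yc - s.y_med) / (s.y_max - s.y_med) * self.lambda_max,
            )
        lam = np.clip(lam, -self.lambda_max, self.lambda_max)
        return lam if lam.ndim else float(lam)

    def step_factor(self, residual, y):
        """Multiplier exp(sgn(r)·λ(y)); exactly 1 at residual 0."""
        r = np.asarray(residual, dtype=float)
        if not np.all(np.isfinite(r)):
            raise InputError("residuals must be finite")
        lam = np.asarray(self.lambda_of_age(y), dtype=float)
        out = np.exp(np.sign(r) * lam)
        return out if out.ndim else float(out)

    def to_record(self) -> dict:
        """Plain key-value record for experiment reports."""
        return {
            "y_min": self.stats.y_min,
            "y_max": self.stats.y_max,
            "y_med": self.stats.y_med,
            "lambda_max": self.lambda_max,
            "mode": self.mode,
        }


def make_schedule(
    stats: AgeStats, lambda_max: float, mode: Mode = "piecewise_median"
) -> LambdaSchedule:
    """Construct a skew schedule from cohort age statistics."""
    return LambdaSchedule(stats=stats, lambda_max=float(lambda_max), mode=mode)


def lambda_of_age(schedule: LambdaSchedule, y):
    return schedule.lambda_of_age(y)


def step_factor(schedule: LambdaSchedule, residual, y):
    return schedule.step_factor(residual, y)


def step_factor_two_height(params: StepParams, residual):
    """Generic two-height step: λ0 on negative residuals, λ1 on nonnegative.

    Residual 0 takes the nonnegative height, matching the indicator-function
    definition; the exponential schedule form instead returns exactly 1 at 0,
    which is loss-equivalent since the base loss vanishes there.
    """
    r = np.asarray(residual, dtype=float)
    out = np.where(r < 0, params.lambda0, params.lambda1)
    return out if out.ndim else float(out)


def with_lambda_max(schedule: LambdaSchedule, new_lambda_max: float) -> LambdaSchedule:
    """Copy of *schedule* with an updated skew bound (original untouched)."""
    if not (math.isfinite(new_lambda_max) and new_lambda_max >= 0):
        raise ConfigurationError(
            f"lambda_max must be a finite nonnegative real, got {new_lambda_max!r}"
        )
    return replace(schedule, lambda_max=float(new_lambda_max))
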