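"""Symmetric and skewed regression losses.

The skewed loss is the symmetric base loss times the age- and sign-dependent
step factor:

    L~(y, ŷ) = L(y, ŷ) · exp(sgn(y − ŷ) · λ(y))

With λ_max = 0 the factor is identically 1 and the skewed loss reduces
bit-exactly to the base loss.

Gradient contract: the step factor is piecewise constant in ŷ, so away from
the (measure-zero) point y = ŷ the derivative of the skewed loss w.r.t. ŷ is
the factor times the base-loss derivative.  ``grad_wrt_prediction`` exposes
exactly that product, which is what the gradient-descent trainers consume.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

from .errors import InputError
from .lambda_schedule import LambdaSchedule

BaseKind = Literal["l1", "l2"]

__all__ = ["SkewedLossSpec", "base_loss", "skewed_sample_loss", "batch_loss"]


def _check_finite(*arrays) -> None:
    for a in arrays:
        if not np.all(np.isfinite(a)):
            raise InputError("loss inputs must be finite")


def base_loss(kind: BaseKind, y, y_hat):
    """Symmetric base loss: L1 = |y − ŷ|, L2 = (y − ŷ)²."""
    y = np.asarray(y, dtype=float)
    y_hat = np.asarray(y_hat, dtype=float)
    _check_finite(y, y_hat)
    r = y - y_hat
    if kind == "l1":
        out = np.abs(r)
    elif kind == "l2":
        out = r * r
    else:
        raise InputError(f"unknown base loss kind {kind!r}")
    return out if out.ndim else float(out)


def _base_grad(kind: BaseKind, r):
    # d base / d ŷ with r = y − ŷ
    if kind == "l1":
        return -np.sign(r)
    return -2.0 * r


@dataclass(frozen=True)
class SkewedLossSpec:
    """Base loss kind plus a skew schedule.  Default base is L1, the loss the
    brain-age literature evaluates (MAE) and the one used throughout."""

    base: BaseKind
    schedule: LambdaSchedule

    def sample_loss(self, y, y_hat):
        """Per-sample skewed loss: base_loss · step_factor."""
        y = np.asarray(y, dtype=float)
        y_hat = np.asarray(y_hat, dtype=float)
        b = base_loss(self.base, y, y_hat)
        if self.schedule.lambda_max == 0.0:
            return b  # bit-exact reduction to the symmetric loss
        f = self.schedule.step_factor(y - y_hat, y)
        out = b * f
        return out if np.ndim(out) else float(out)

    def batch_loss(self, y, y_hat) -> float:
        y = np.atleast_1d(np.asarray(y, dtype=float))
        y_hat = np.atleast_1d(np.asarray(y_hat, dtype=float))
        if y.size == 0:
            raise InputError("empty batch")
        if y.shape != y_hat.shape:
            raise InputError(f"length mismatch: {y.shape} vs {y_hat.shape}")
        return float(np.mean(self.sample_loss(y, y_hat)))

    def grad_wrt_prediction(self, y, y_hat):
        """d(sample loss)/dŷ, elementwise; the step factor is treated as
        constant in ŷ (zero derivative almost everywhere)."""
        y = np.asarray(y, dtype=float)
        y_hat = np.asarray(y_hat, dtype=float)
        _check_finite(y, y_hat)
        r = y - y_hat
        g = _base_grad(self.base, r)
        if self.schedule.lambda_max == 0.0:
            return g
        return g * self.schedule.step_factor(r, y)


def skewed_sample_loss(spec: SkewedLossSpec, y, y_hat):
    return spec.sample_loss(y, y_hat)


def batch_loss(spec: SkewedLossSpec, y, y_hat) -> float:
    return spec.batch_loss(y, y_hat)
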