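"""Dynamic-lambda training: a three-stage controller for the skew bound λ_max.

A skewed loss removes the negative age-delta correlation (ADC) only if the
skew bound λ_max is right for the model and data at hand, and that value
cannot be known before training.  The controller tunes λ_max during training
so the validation-set ADC approaches zero:

* **Stage 1** (epochs < α): plain training with the initial λ_max, so early,
  uninformative ADC estimates never drive updates.
* **Stage 2** (α ≤ epoch < β): every ε epochs, measure validation ADC and
  nudge λ_max multiplicatively — divide by η when ADC > θ (skew overshot),
  multiply by η when ADC < −θ (not enough skew).  Each (λ_max, ADC) pair is
  saved.
* **Stage 3** (epoch ≥ β): every ε epochs, fit a straight line through all
  saved (λ_max, ADC) pairs and jump to its root — the λ_max at which the
  predicted ADC is zero.

λ_max is clipped to [λ_floor, λ_ceiling] throughout: the regression root from
a near-flat stage-3 fit can otherwise explode the loss scale.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Literal, Optional

import numpy as np
from scipy import stats as _sps

from .errors import ConfigurationError, TrainingError, UndefinedCorrelationError
from .lambda_schedule import AgeStats, make_schedule, with_lambda_max
from .metrics import EvalReport
from .models import Adam, GradientRegressor
from .skewed_loss import SkewedLossSpec
from .synthetic import Dataset

logger = logging.getLogger(__name__)

__all__ = [
    "TrainerConfig",
    "LambdaTrace",
    "stage2_update",
    "stage3_update",
    "evaluate_checkpoint",
    "train",
]


@dataclass(frozen=True)
class TrainerConfig:
    """Controller and optimization hyperparameters.

    Controller defaults follow the published recipe: 400 epochs split in
    three stages at α = 150 and β = 300, checkpoints every ε = 5 epochs,
    correlation threshold θ = 0.15, multiplier η = 1.5, initial λ_max = 1.
    Optimization defaults: Adam, learning rate 0.01 halved every 50 epochs,
    batch size 16, L2 weight decay 0.001, L1 base loss.

    Set ``dynamic=False`` for a plain gradient-descent loop with the skew
    bound frozen at ``lambda_max_init`` (use 0 for fully symmetric training).
    ``theta = math.inf`` likewise disables stage-2 adjustments.
    """

    gamma: int = 400
    alpha: int = 150
    beta: int = 300
    epsilon: int = 5
    theta: float = 0.15
    eta: float = 1.5
    lambda_max_init: float = 1.0
    adc_method: Literal["pearson", "spearman"] = "pearson"
    seed: int = 0
    dynamic: bool = True
    lambda_floor: float = 1e-3
    lambda_ceiling: float = 20.0
    base: Literal["l1", "l2"] = "l1"
    mode: Literal["linear", "piecewise_median"] = "piecewise_median"
    lr: float = 0.01
    lr_decay: float = 0.5
    lr_decay_every: int = 50
    batch_size: int = 16
    weight_decay: float = 1e-3
    log_every_epoch: bool = False

    def __post_init__(self) -> None:
        if not (0 < self.alpha < self.beta < self.gamma):
            raise ConfigurationError(
                f"need 0 < alpha < beta < gamma, got {self.alpha}, {self.beta}, {self.gamma}"
            )
        if self.epsilon < 1:
            raise ConfigurationError("epsilon must be ≥ 1")
        if not self.theta > 0:
            raise ConfigurationError("theta must be positive (math.inf disables updates)")
        if not self.eta > 1:
            raise ConfigurationError("eta must be > 1")
        if self.lambda_max_init < 0:
            raise ConfigurationError("lambda_max_init must be nonnegative")
        if not (0 < self.lambda_floor < self.lambda_ceiling):
            raise ConfigurationError("need 0 < lambda_floor < lambda_ceiling")


@dataclass
class LambdaTrace:
    """Paired history of λ_max values (M) and validation ADC values (N)."""

    M: list = field(default_factory=list)
    N: list = field(default_factory=list)
    epochs: list = field(default_factory=list)

    def append(self, epoch: int, lambda_max: float, adc_value: float) -> None:
        self.epochs.append(epoch)
        self.M.append(lambda_max)
        self.N.append(adc_value)

    def __len__(self) -> int:
        return len(self.M)


def stage2_update(lambda_max: float, adc: float, theta: float, eta: float,
                  lambda_floor: float = 1e-3, lambda_ceiling: float = 20.0) -> float:
    """Heuristic multiplicative update: divide by η when ADC > θ, multiply by
    η when ADC < −θ, leave unchanged inside the band."""
    if adc > theta:
        lambda_max = lambda_max / eta
    elif adc < -theta:
        lambda_max = lambda_max * eta
    return float(np.clip(lambda_max, lambda_floor, lambda_ceiling))


def stage3_update(trace: LambdaTrace, current: float,
                  lambda_floor: float = 1e-3, lambda_ceiling: float = 20.0,
                  slope_tol: float = 1e-8) -> float:
    """Regression-based update: fit ADC on λ_max over the whole trace and
    return the λ_max at which the fitted line crosses zero.

    Falls back to the current λ_max (with a warning) when the trace has fewer
    than two distinct λ_max values or the fitted slope is below tolerance.
    """
    M = np.asarray(trace.M, dtype=float)
    N = np.asarray(trace.N, dtype=float)
    if M.size < 2 or np.ptp(M) == 0.0:
        logger.warning("stage-3 fit degenerate (%d points, ptp=%.3g); keeping λ_max=%.4g",
                       M.size, float(np.ptp(M)) if M.size else 0.0, current)
        return float(np.clip(current, lambda_floor, lambda_ceiling))
    fit = _sps.linregress(M, N)
    if abs(fit.slope) < slope_tol:
        logger.warning("stage-3 slope %.3g below tolerance; keeping λ_max=%.4g",
                       fit.slope, current)
        return float(np.clip(current, lambda_floor, lambda_ceiling))
    root = -fit.intercept / fit.slope
    return float(np.clip(root, lambda_floor, lambda_ceiling))


def evaluate_checkpoint(model: GradientRegressor, val_data: Dataset,
                        adc_method: str = "pearson") -> EvalReport:
    """MAE and ADC of the current model on the validation set."""
    return EvalReport.from_predictions(model.predict(val_data.features),
                                       val_data.ages, adc_method)


def _stage_of(epoch: int, cfg: TrainerConfig) -> int:
    if epoch < cfg.alpha:
        return 1
    if epoch < cfg.beta:
        return 2
    return 3


def train(
    model: GradientRegressor,
    train_data: Dataset,
    val_data: Dataset,
    config: TrainerConfig,
    loss_spec: Optional[SkewedLossSpec] = None,
) -> tuple[GradientRegressor, LambdaTrace, list[dict]]:
    """Run the three-stage dynamic-lambda training loop.

    The skew schedule's age statistics come from the *training* ages only
    (no leakage of validation or test statistics).  One integer seed controls
    model initialization and batch shuffling, so runs are reproducible.

    Returns the trained model, the (λ_max, ADC) trace, and a per-checkpoint
    log (per-epoch if ``config.log_every_epoch``) with columns
    epoch / stage / lambda_max / val_mae / val_adc.
    """
    rng = np.random.default_rng(config.seed)
    model.initialize(train_data.p, rng)
    model.prepare(train_data.features, train_data.ages)

    if loss_spec is None:
        schedule = make_schedule(AgeStats.from_ages(train_data.ages),
                                 config.lambda_max_init, config.mode)
        loss_spec = SkewedLossSpec(base=config.base, schedule=schedule)

    opt = Adam(model.params, weight_decay=config.weight_decay)
    trace = LambdaTrace()
    log: list[dict] = []
    X, y = train_data.features, train_data.ages
    n = train_data.n
    undefined_streak = 0

    for epoch in range(1, config.gamma + 1):
        lr = config.lr * config.lr_decay ** ((epoch - 1) // config.lr_decay_every)
        order = rng.permutation(n)
        for start in range(0, n, config.batch_size):
            idx = order[start:start + config.batch_size]
            Xb, yb = X[idx], y[idx]
            yhat = model.predict(Xb)
            dl = loss_spec.grad_wrt_prediction(yb, yhat) / idx.size
            opt.step(model.params, model.backward(Xb, dl), lr)

        stage = _stage_of(epoch, config)
        is_checkpoint = config.dynamic and (
            (stage == 2 and (epoch - config.alpha) % config.epsilon == 0)
            or (stage == 3 and (epoch - config.beta) % config.epsilon == 0)
        )

        row = {"epoch": epoch, "stage": stage,
               "lambda_max": loss_spec.schedule.lambda_max,
               "val_mae": math.nan, "val_adc": math.nan}

        if is_checkpoint:
            lam = loss_spec.schedule.lambda_max
            try:
                report = evaluate_checkpoint(model, val_data, config.adc_method)
            except UndefinedCorrelationError:
                undefined_streak += 1
                logger.warning("validation ADC undefined at epoch %d (streak %d); "
                               "update skipped", epoch, undefined_streak)
                if undefined_streak >= 3:
                    raise TrainingError(
                        "validation ADC undefined for 3 consecutive checkpoints; "
                        "model predictions have collapsed to a constant"
                    )
            else:
                undefined_streak = 0
                trace.append(epoch, lam, report.adc)
                row["val_mae"], row["val_adc"] = report.mae, report.adc
                if stage == 2:
                    new_lam = stage2_update(lam, report.adc, config.theta, config.eta,
                                            config.lambda_floor, config.lambda_ceiling)
                else:
                    new_lam = stage3_update(trace, lam,
                                            config.lambda_floor, config.lambda_ceiling)
                if new_lam != lam:
                    logger.debug("epoch %d stage %d: λ_max %.4g → %.4g (ADC %.3f)",
                                 epoch, stage, lam, new_lam, report.adc)
                    loss_spec = SkewedLossSpec(
                        base=loss_spec.base,
                        schedule=with_lambda_max(loss_spec.schedule, new_lam),
                    )
                row["lambda_max"] = new_lam
        elif config.log_every_epoch:
            try:
                report = evaluate_checkpoint(model, val_data, config.adc_method)
                row["val_mae"], row["val_adc"] = report.mae, report.adc
            except UndefinedCorrelationError:
                pass

        if is_checkpoint or config.log_every_epoch:
            log.append(row)

    return model, trace, log
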