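"""Repeated-run experiment harness: three arms over many stratified splits.

Mirrors the published evaluation design at desk scale: each dataset is split
in ``n_splits`` different stratified ways; on each split every arm is trained
``runs_per_split`` times (different weight initializations); per-split metrics
are run-averaged; arms are compared across splits with paired tests.

Arms:

* ``normal`` — symmetric loss, no correction (the MAE lower bound).
* ``two_stage`` — the normal-arm model with the post-hoc linear correction
  fitted on the validation split and applied to the test split.
* ``skewed`` — skewed loss trained under the dynamic-lambda controller.

All arms consume byte-identical splits within a split index, so cross-arm
comparisons are exactly paired.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from typing import Literal, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as _sps

from .dynamic_lambda import TrainerConfig, train
from .errors import InputError, SkewageError
from .metrics import EvalReport, adc, mae
from .models import LinearRegressor, MLPRegressor
from .synthetic import Dataset, SynthConfig, generate, split_stratified

logger = logging.getLogger(__name__)

Arm = Literal["normal", "two_stage", "skewed"]

__all__ = ["ExperimentPlan", "run_experiment", "ensemble_evaluate", "compare_arms"]


@dataclass(frozen=True)
class ExperimentPlan:
    """Full experimental design: data source, split/run counts, arms."""

    synth: Optional[SynthConfig] = None
    csv_path: Optional[str] = None
    n_splits: int = 20
    runs_per_split: int = 5
    arms: tuple = ("normal", "two_stage", "skewed")
    trainer: TrainerConfig = field(default_factory=TrainerConfig)
    model: Literal["linear", "mlp"] = "linear"
    fractions: tuple = (0.8, 0.1, 0.1)
    n_bins: int = 5
    master_seed: int = 0
    include_approach1: bool = False

    def __post_init__(self) -> None:
        if self.n_splits < 1 or self.runs_per_split < 1:
            raise InputError("n_splits and runs_per_split must be ≥ 1")
        if not self.arms:
            raise InputError("arms must be non-empty")
        unknown = set(self.arms) - {"normal", "two_stage", "skewed"}
        if unknown:
            raise InputError(f"unknown arms: {sorted(unknown)}")

    def load_data(self) -> Dataset:
        if self.csv_path is not None:
            return Dataset.from_csv(self.csv_path)
        cfg = self.synth if self.synth is not None else SynthConfig(seed=self.master_seed)
        return generate(cfg)


def _make_model(kind: str):
    return LinearRegressor() if kind == "linear" else MLPRegressor()


def _run_seed(master_seed: int, split: int, run: int, arm_offset: int) -> int:
    # distinct, reproducible, and < 2**31
    return (master_seed * 1_000_003 + split * 1_009 + run * 13 + arm_offset) % (2**31 - 1)


def run_experiment(plan: ExperimentPlan) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Execute the full plan; returns (long-format results, per-arm summary).

    The long table has one row per split × run × arm with test-set MAE/ADC.
    The summary has per-arm mean ± sd of the split-averaged metrics (runs
    averaged within a split first), the published tables' format.
    """
    from .two_stage import apply_correction_approach2, fit_correction_approach2

    data = plan.load_data()
    rows: list[dict] = []
    failures = 0
    total = plan.n_splits * plan.runs_per_split * len(plan.arms)

    for split in range(plan.n_splits):
        split_seed = _run_seed(plan.master_seed, split, 0, 0)
        tr, va, te = split_stratified(data, plan.fractions, plan.n_bins, seed=split_seed)
        for run in range(plan.runs_per_split):
            # the symmetric model backs both the normal and the two-stage arm
            sym_preds = None
            if "normal" in plan.arms or "two_stage" in plan.arms:
                cfg = dataclasses.replace(
                    plan.trainer, dynamic=False, lambda_max_init=0.0,
                    seed=_run_seed(plan.master_seed, split, run, 1),
                )
                try:
                    model, _, _ = train(_make_model(plan.model), tr, va, cfg)
                    sym_preds = (model.predict(va.features), model.predict(te.features))
                except SkewageError as exc:
                    logger.warning("split %d run %d symmetric training failed: %s",
                                   split, run, exc)

            for arm in plan.arms:
                try:
                    if arm == "normal":
                        if sym_preds is None:
                            raise SkewageError("symmetric model unavailable")
                        report = EvalReport.from_predictions(
                            sym_preds[1], te.ages, plan.trainer.adc_method)
                        lam = 0.0
                    elif arm == "two_stage":
                        if sym_preds is None:
                            raise SkewageError("symmetric model unavailable")
                        corr = fit_correction_approach2(sym_preds[0], va.ages)
                        report = EvalReport.from_predictions(
                            apply_correction_approach2(corr, sym_preds[1]),
                            te.ages, plan.trainer.adc_method)
                        lam = 0.0
                    else:  # skewed
                        cfg = dataclasses.replace(
                            plan.trainer,
                            seed=_run_seed(plan.master_seed, split, run, 2),
                        )
                        model, trace, _ = train(_make_model(plan.model), tr, va, cfg)
                        report = EvalReport.from_predictions(
                            model.predict(te.features), te.ages, plan.trainer.adc_method)
                        lam = trace.M[-1] if len(trace) else cfg.lambda_max_init
                    rows.append({
                        "split_id": split, "run_id": run, "method": arm,
                        "loss": plan.trainer.base, "mae": report.mae,
                        "adc": report.adc, "adc_method": report.adc_method,
                        "n": report.n, "final_lambda_max": lam,
                    })
                except SkewageError as exc:
                    failures += 1
                    logger.warning("split %d run %d arm %s failed: %s", split, run, arm, exc)
                    if failures > 0.2 * total:
                        raise SkewageError(
                            f"{failures}/{total} runs failed (> 20%); aborting"
                        ) from exc

    results = pd.DataFrame(rows)
    summary = summarize(results)
    return results, summary


def summarize(results: pd.DataFrame) -> pd.DataFrame:
    """Per-arm mean ± sd of split-averaged MAE and ADC."""
    per_split = results.groupby(["method", "split_id"])[["mae", "adc"]].mean().reset_index()
    out = per_split.groupby("method").agg(
        mae_mean=("mae", "mean"), mae_sd=("mae", "std"),
        adc_mean=("adc", "mean"), adc_sd=("adc", "std"),
        n_splits=("split_id", "nunique"),
    ).reset_index()
    return out


def ensemble_evaluate(predictions: Sequence[np.ndarray], y_test,
                      adc_method: str = "pearson") -> EvalReport:
    """Average the per-run predictions subject-wise, then evaluate the
    ensemble as a single predictor."""
    if len(predictions) < 2:
        raise InputError("ensemble needs at least 2 runs")
    preds = [np.atleast_1d(np.asarray(p, dtype=float)) for p in predictions]
    y = np.atleast_1d(np.asarray(y_test, dtype=float))
    if any(p.shape != y.shape for p in preds):
        raise InputError("misaligned subject sets across runs")
    mean_pred = np.mean(preds, axis=0)
    return EvalReport.from_predictions(mean_pred, y, adc_method)


def compare_arms(results: pd.DataFrame,
                 tests: Sequence[str] = ("wilcoxon_signed_rank", "paired_t")) -> pd.DataFrame:
    """Paired significance tests between arms on split-averaged metrics.

    Two-sided throughout.  All-zero differences make the signed-rank statistic
    degenerate; those rows report p = 1 with a note.
    """
    per_split = results.groupby(["method", "split_id"])[["mae", "adc"]].mean()
    arms = sorted(results["method"].unique())
    rows = []
    for i, a in enumerate(arms):
        for b in arms[i + 1:]:
            xa = per_split.loc[a]
            xb = per_split.loc[b]
            common = xa.index.intersection(xb.index)
            if len(common) < 6:
                raise InputError(
                    f"need ≥ 6 paired splits for {a} vs {b}, got {len(common)}"
                )
            if len(common) < len(xa) or len(common) < len(xb):
                raise InputError(f"unpaired splits between {a} and {b}")
            for metric in ("mae", "adc"):
                diff = (xa.loc[common, metric] - xb.loc[common, metric]).to_numpy()
                for test in tests:
                    note = ""
                    if test == "wilcoxon_signed_rank":
                        if np.allclose(diff, 0.0):
                            p = 1.0
                            note = "all differences zero; test degenerate"
                        else:
                            p = float(_sps.wilcoxon(diff).pvalue)
                    elif test == "paired_t":
                        if np.allclose(diff, diff[0]):
                            # zero-variance differences: t is ±inf unless the
                            # common difference is itself 0
                            p = 1.0 if np.allclose(diff, 0.0) else 0.0
                            note = "zero-variance differences"
                        else:
                            p = float(_sps.ttest_rel(xa.loc[common, metric],
                                                     xb.loc[common, metric]).pvalue)
                    else:
                        raise InputError(f"unknown test {test!r}")
                    rows.append({"arm_a": a, "arm_b": b, "metric": metric,
                                 "test": test, "p_value": p, "n_pairs": len(common),
                                 "note": note})
    return pd.DataFrame(rows)
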