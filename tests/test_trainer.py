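"""The three-stage dynamic-lambda controller and its update rules."""

import math

import numpy as np
import pytest

from skewage import (
    ConfigurationError,
    LambdaTrace,
    LinearRegressor,
    MLPRegressor,
    SynthConfig,
    TrainerConfig,
    TrainingError,
    evaluate_checkpoint,
    generate,
    mae,
    split_stratified,
    stage2_update,
    stage3_update,
    train,
)
from skewage.models import Adam


# small-but-real controller config: three stages, checkpoints every 2 epochs
FAST = dict(gamma=30, alpha=10, beta=20, epsilon=2)


@pytest.fixture(scope="module")
def small_splits():
    ds = generate(SynthConfig(n=200, seed=13))
    return split_stratified(ds, seed=13)


class TestStage2Update:
    def test_within_band_unchanged(self):
        assert stage2_update(1.0, 0.0, 0.15, 1.5) == 1.0

    def test_negative_adc_multiplies(self):
        assert stage2_update(1.0, -0.30, 0.15, 1.5) == 1.5

    def test_positive_adc_divides(self):
        assert stage2_update(1.5, 0.30, 0.15, 1.5) == 1.0

    def test_result_clipped_to_bounds(self):
        assert stage2_update(15.0, -0.5, 0.15, 2.0, lambda_ceiling=20.0) == 20.0
        assert stage2_update(1e-3, 0.5, 0.15, 2.0, lambda_floor=1e-3) == 1e-3


class TestStage3Update:
    def test_two_point_root(self):
        trace = LambdaTrace(M=[1.0, 2.0], N=[-0.2, 0.2])
        # line: ADC = 0.4·λ − 0.6, root at 1.5
        assert stage3_update(trace, current=2.0) == pytest.approx(1.5)

    def test_flat_adc_keeps_current(self):
        trace = LambdaTrace(M=[1.0, 2.0, 3.0], N=[0.0, 0.0, 0.0])
        assert stage3_update(trace, current=2.0) == 2.0

    def test_identical_lambdas_keep_current_with_warning(self, caplog):
        trace = LambdaTrace(M=[1.0, 1.0, 1.0], N=[-0.3, -0.1, 0.1])
        with caplog.at_level("WARNING"):
            assert stage3_update(trace, current=1.0) == 1.0
        assert "degenerate" in caplog.text

    def test_root_matches_independent_normal_equations(self):
        M = [1.0, 1.5, 2.25]
        N = [-0.3, -0.1, 0.15]
        trace = LambdaTrace(M=list(M), N=list(N))
        A = np.c_[M, np.ones(3)]
        slope, intercept = np.linalg.lstsq(A, np.array(N), rcond=None)[0]
        assert stage3_update(trace, current=2.0) == pytest.approx(-intercept / slope)

    def test_root_clipped_to_ceiling(self):
        trace = LambdaTrace(M=[1.0, 2.0], N=[-0.5, -0.49])
        assert stage3_update(trace, current=2.0, lambda_ceiling=20.0) == 20.0


class TestTrainerConfig:
    @pytest.mark.parametrize(
        "kwargs",
        [dict(alpha=300, beta=150), dict(alpha=0), dict(epsilon=0),
         dict(theta=0.0), dict(eta=1.0), dict(lambda_max_init=-1.0),
         dict(lambda_floor=0.0)],
    )
    def test_invalid_rejected(self, kwargs):
        with pytest.raises(ConfigurationError):
            TrainerConfig(**kwargs)

    def test_infinite_theta_allowed_as_update_disabler(self):
        cfg = TrainerConfig(theta=math.inf)
        assert math.isinf(cfg.theta)


class TestTrainLoop:
    def test_trace_length_matches_checkpoint_count(self, small_splits):
        tr, va, _ = small_splits
        cfg = TrainerConfig(seed=1, **FAST)
        _, trace, log = train(LinearRegressor(), tr, va, cfg)
        # stage 2: epochs 10,12,...,18 → 5; stage 3: 20,22,...,30 → 6
        assert len(trace) == 5 + 6
        assert len(log) == len(trace)
        assert trace.epochs[0] == cfg.alpha
        assert trace.epochs[-1] == cfg.gamma

    def test_lambda_stays_within_bounds(self, small_splits):
        tr, va, _ = small_splits
        cfg = TrainerConfig(seed=2, **FAST)
        _, trace, _ = train(LinearRegressor(), tr, va, cfg)
        assert all(cfg.lambda_floor <= m <= cfg.lambda_ceiling for m in trace.M)
        assert all(-1.0 <= n <= 1.0 for n in trace.N)

    def test_stage2_multiplies_while_adc_below_minus_theta(self, small_splits):
        """While the measured ADC stays below −θ, successive stage-2 λ_max
        values must be non-decreasing (the multiply branch fires)."""
        tr, va, _ = small_splits
        cfg = TrainerConfig(seed=3, gamma=60, alpha=10, beta=50, epsilon=2)
        _, trace, _ = train(LinearRegressor(), tr, va, cfg)
        stage2 = [(m, n) for e, m, n in zip(trace.epochs, trace.M, trace.N) if e < cfg.beta]
        for (m0, n0), (m1, _) in zip(stage2, stage2[1:]):
            if n0 < -cfg.theta:
                assert m1 >= m0

    def test_disabled_controller_equals_reference_symmetric_loop(self, small_splits):
        """With dynamic=False and λ_max = 0 the trainer must be a plain
        mini-batch gradient-descent loop: byte-identical predictions to an
        independent reimplementation under the same seed."""
        tr, va, _ = small_splits
        cfg = TrainerConfig(seed=5, dynamic=False, lambda_max_init=0.0, **FAST)
        model, trace, _ = train(LinearRegressor(), tr, va, cfg)
        assert len(trace) == 0

        # reference loop, written independently of the trainer
        rng = np.random.default_rng(cfg.seed)
        ref = LinearRegressor()
        ref.initialize(tr.p, rng)
        ref.prepare(tr.features, tr.ages)
        opt = Adam(ref.params, weight_decay=cfg.weight_decay)
        for epoch in range(1, cfg.gamma + 1):
            lr = cfg.lr * cfg.lr_decay ** ((epoch - 1) // cfg.lr_decay_every)
            order = rng.permutation(tr.n)
            for s in range(0, tr.n, cfg.batch_size):
                idx = order[s:s + cfg.batch_size]
                r = tr.ages[idx] - ref.predict(tr.features[idx])
                dl = -np.sign(r) / idx.size
                opt.step(ref.params, ref.backward(tr.features[idx], dl), lr)
        assert np.array_equal(model.predict(va.features), ref.predict(va.features))

    def test_same_seed_reproduces_identical_run(self, small_splits):
        tr, va, _ = small_splits
        cfg = TrainerConfig(seed=8, **FAST)
        m1, t1, _ = train(LinearRegressor(), tr, va, cfg)
        m2, t2, _ = train(LinearRegressor(), tr, va, cfg)
        assert t1.M == t2.M and t1.N == t2.N
        assert np.array_equal(m1.predict(va.features), m2.predict(va.features))

    def test_mlp_trains_and_reduces_error(self, small_splits):
        tr, va, _ = small_splits
        cfg = TrainerConfig(seed=4, dynamic=False, lambda_max_init=0.0, **FAST)
        model, _, _ = train(MLPRegressor(hidden=8), tr, va, cfg)
        # far better than the age-range scale; the prepare() intercept alone
        # gives ≈ sd(ages) ≈ 20
        assert mae(model.predict(va.features), va.ages) < 10.0

    def test_persistently_undefined_adc_raises_training_error(self, small_splits):
        """A model whose validation delta is constant (here: oracle
        predictions, delta ≡ 0) leaves the ADC undefined; after 3 consecutive
        undefined checkpoints the trainer must abort."""
        tr, va, _ = small_splits
        ages_by_id = dict(zip(map(tuple, va.features), va.ages))

        class OracleModel(LinearRegressor):
            def predict(self, X):
                return np.array([ages_by_id.get(tuple(row), 42.0) for row in X])

        cfg = TrainerConfig(seed=0, **FAST)
        with pytest.raises(TrainingError, match="collapsed"):
            train(OracleModel(), tr, va, cfg)

    def test_checkpoint_report_delegates_to_metrics(self, small_splits):
        tr, va, _ = small_splits
        cfg = TrainerConfig(seed=6, dynamic=False, lambda_max_init=0.0, **FAST)
        model, _, _ = train(LinearRegressor(), tr, va, cfg)
        report = evaluate_checkpoint(model, va, "pearson")
        from skewage import adc as adc_fn
        preds = model.predict(va.features)
        assert report.mae == pytest.approx(mae(preds, va.ages))
        assert report.adc == pytest.approx(adc_fn(preds, va.ages))
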