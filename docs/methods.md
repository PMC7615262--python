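# Methods

## Model and assumptions

The package targets the bias that appears whenever a regressor is trained
with a symmetric loss on noisy age-related features: predicted age is
attenuated toward the cohort mean, so the delta δ = ŷ − y correlates
negatively with age (ADC < 0). The correction assumes only that the model is
trained by gradient descent on a per-sample loss, and that validation and
test sets are drawn from similar distributions — the validation set is the
optimization target for both correction approaches, and neither is expected
to survive a deliberate train/test distribution shift (the
`experiment --shift` design demonstrates exactly that failure mode).

### Skew schedule

λ(y) maps age to a skew in [−λ_max, +λ_max], non-decreasing in age.
Two shapes are implemented:

* `linear`: λ = (2g − 1)·λ_max with g = (y − y_min)/(y_max − y_min); zero at
  the midpoint of the age range.
* `piecewise_median` (default): two linear pieces with λ(y_med) = 0, so even
  a heavily skewed cohort has roughly equal numbers of positive- and
  negative-skew subjects. The formal definition of the skewed loss uses this
  shape, which is why it is the default.

Age statistics (min, max, median) are computed from the **training split
only**; using the whole dataset would leak validation/test statistics into
the loss. Ages outside the training range clamp to the boundary skew rather
than extrapolating, so the advertised bound |λ| ≤ λ_max holds for any test
subject.

`sgn(0)` is left ambiguous by the two-sided definition of the step factor;
the implementation returns exactly 1 at residual 0. The base loss is 0 there
for L1 and L2, so any finite factor gives the same loss; 1 keeps the factor
symmetric and the batch loss continuous.

### Gradient treatment

The step factor is piecewise constant in ŷ, so its derivative is zero almost
everywhere; the trainers use d L~/dŷ = factor · d L/dŷ and ignore the jump at
y = ŷ (measure zero, and the L1 subgradient is itself set-valued there).
This makes the loss usable with plain analytic gradients — no autodiff
machinery is needed, and any autodiff implementation would agree almost
everywhere.

## Dynamic-lambda controller

Stage boundaries default to α = γ/3 ≈ 150 and β = 2γ/3 = 300 of γ = 400
epochs; checkpoints every ε = 5 epochs; threshold θ = 0.15; multiplier
η = 1.5. These are the published recipe and the defaults here. Stage-2
checkpoints fall at (epoch − α) mod ε = 0, stage-3 at (epoch − β) mod ε = 0,
with validation ADC measured **after** the epoch's gradient steps. The
stage-3 line is fitted to *all* saved (λ_max, ADC) pairs, stage-2's and the
ones stage 3 itself appends, and its zero-ADC root becomes the new λ_max.

Numerical guards, all config-overridable:

* λ_max is clipped to [1e−3, 20]. A near-flat stage-3 fit has a root at
  ±∞; unclipped it would explode the loss scale. 20 corresponds to a factor
  e²⁰ ≈ 5·10⁸ between over- and underprediction penalties — far beyond any
  useful skew.
* A stage-3 slope below 1e−8 (or fewer than two distinct λ_max values in the
  trace) keeps the current λ_max, with a warning. This occurs benignly when
  stage 2 never left the θ-band, so all saved λ_max are identical.
* An undefined validation ADC (constant delta, e.g. a collapsed or exactly
  oracle model) skips that checkpoint; three consecutive undefined
  checkpoints abort training with a typed error.

`dynamic=False` freezes λ_max (0 gives the symmetric baseline arm); the loop
is then byte-identical to a plain mini-batch gradient-descent loop under the
same seed, which the test suite verifies against an independent
reimplementation.

## Reference models

The bias is a property of symmetric-loss regression, not of any
architecture, so desk-scale models suffice to exercise the controller and
keep the full 20-split × 3-arm comparison in minutes:

* `LinearRegressor` — ŷ = Zw + b over inputs standardized by training-set
  statistics. Standardization is a conditioning choice, not a modeling one:
  raw all-positive correlated features couple the weights to the intercept
  and make L1 gradient descent crawl.
* `MLPRegressor` — one tanh hidden layer (default width 16) over the same
  standardized inputs.

Both initialize the output intercept at the mean training age so early-epoch
ADC estimates are informative, and train with Adam (lr 0.01 halved every 50
epochs, batch 16, L2 weight decay 0.001) — the published optimization
settings. One integer seed drives model initialization and batch shuffling.

## Synthetic cohort generator

Each feature is age plus a random per-feature intercept plus i.i.d. Gaussian
noise (`mild_nonlinear` adds a small quadratic term). This reproduces the
one statistical property the method needs — regression dilution with a known
closed form:

    R = σ_y²/(σ_y² + σ_e²),   ADC = (R−1)σ_y / √((R−1)²σ_y² + R²σ_e²)

`theoretical_adc` implements this oracle; the generator is validated against
it empirically (|ADC_emp − ADC_theory| < 0.03 at n = 10,000 for R = 0.5).

Defaults mimic a public aging cohort at desk scale: n = 650 subjects, ages
uniform on (18, 88) years, p = 5 features, noise_sd = 13.2 years. With
σ_y = 70/√12 ≈ 20.2, that noise gives a per-feature attenuation slope
R ≈ 0.7 and a population ADC ≈ −0.28 for the multivariate OLS predictor —
a clearly biased but trainable regime. Age distributions `skew_young` /
`skew_old` (exponentially tilted, default rate 4) emulate cohorts
concentrated at one end of the age range; `truncated_normal` gives a
bell-shaped cohort.

What the generator does **not** emulate: site/scanner batch effects,
heteroscedastic or age-dependent noise, feature covariance structure beyond
the shared age signal, longitudinal correlation, and anything image-like.
Passing tests therefore show that the estimator and controller behave as the
dilution model predicts — not that any particular MRI pipeline is unbiased.

## Splits and the experiment design

Stratified splits bin subjects by age quantiles (5 bins by default) and
split each bin 80/10/10, so every split covers the age range; per-split age
means stay within ~2 years of the cohort mean at n = 650. The repeated-run
harness mirrors the published design — 20 split seeds × 5 training seeds ×
3 arms, runs averaged within a split before cross-split paired tests
(two-sided Wilcoxon signed-rank and paired t, reported raw). The two-stage
arm reuses the normal arm's trained model, so normal/two-stage comparisons
are paired at the run level as well as the split level.

The distribution-shift mode partitions the cohort at 40 and 60 years and
trains on two groups while testing on the third; its output carries the
caveat that neither correction approach reaches near-zero ADC under such a
shift.

## Problem sizes

Default experiments use the n = 650 / p = 5 cohort with the linear model:
one 400-epoch training run takes under two seconds on one CPU, so the full
acceptance computation (20 runs) completes in well under a minute and the
complete test suite in about one minute. The MLP is provided for
architecture-robustness checks rather than as the default workhorse.

## Known limitations

* The controller targets the validation ADC itself; with small validation
  sets (n ≈ 65) the test-set ADC inherits sampling noise of order
  1/√n ≈ 0.12 around zero even when the controller succeeds.
* Stage-3 trusts a straight-line fit of ADC on λ_max; the true relation is
  monotone but not exactly linear, which the iterated refitting compensates
  for in practice.
* Approach 1 of the post-hoc correction consumes test labels; it is
  implemented for completeness, flagged in its docstring and CLI output, and
  not used by any default path.
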