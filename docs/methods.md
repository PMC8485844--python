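# Methods

## Data model

Observations are follow-up intervals, not patients.  A patient seen at
visits 0, 1, 2 with scores 12, 8, 9 contributes two intervals with rolling
baselines 12 and 8 and changes +4 and −1 (`change = x_(t-1) − x_t`;
positive = improvement).  Intervals missing either endpoint score or the
GRC response at the later visit are dropped individually (complete-interval
analysis); patients are never dropped wholesale, and dropped counts are
logged.  Each scale (PHQ-9, GAD-7) is processed independently, which lets
studies with sparser schedules for one questionnaire still contribute all
their complete intervals for the other.

The GRC is dichotomized per study — 5-level and 3-level variants coexist in
one pooled dataset — with *better* = {a lot better, slightly better,
better} and *not better* = {same, slightly worse, a lot worse, worse}.
For anchor validation the full ordinal coding is kept, with "a lot better"
ranked lowest; Spearman correlations against change are therefore negative,
and adequacy is judged on |rho| ≥ 0.30 per study × interval.  Degenerate
groups (constant GRC or constant change) are flagged rather than fatal.

## The monotone logistic GAMM

Model: `logit P(better) = α + g(baseline) + s(change, baseline) + u_i`,
`u_i ~ N(0, σ_u²)` per patient.

**Basis.**  The interaction smooth `s` is a tensor product of an
*integrated* cubic B-spline margin in change (each margin function is
non-negative, non-decreasing, and zero at the most negative feasible
change) and an ordinary cubic B-spline margin in baseline (non-negative,
partition of unity).  With all tensor coefficients constrained ≥ 0, the
linear predictor is non-decreasing in change at every baseline — the shape
constraint that makes ED inversion well defined — while remaining fully
flexible in how steeply the response rises at different baselines.  `g` is
an unconstrained cubic B-spline, centred over the training sample; no
monotonicity is imposed in the baseline direction.  Default dimensions are
8 × 8 for the tensor and 8 for `g`, with open-uniform knots spanning the
scale-feasible ranges (equally spaced rather than quantile-placed: the
covariates are small integers, and quantile knots would degenerate on
ties).  Because the centred baseline margin sums to zero pointwise, one of
its directions is data-unidentified; the penalized fit leaves such
directions exactly at zero (see Optimization), so predictions are
unaffected.

**Penalties.**  Second-order difference penalties: one isotropic penalty on
the tensor coefficients (sum of the two directional penalties, one
smoothing parameter λ_s) and one on the baseline margin (λ_g).  Shrinkage
is toward bilinear/linear behaviour, which is also the generator's truth —
heavily smoothed fits remain correct for linear truths and the basis keeps
enough freedom for genuinely non-linear baseline dependency.

**Random effects and smoothing selection.**  Random intercepts are
integrated out by a Laplace approximation; the restricted marginal
likelihood adds the penalty pseudo-determinants, the log-determinant of the
joint penalized Hessian (computed via the Schur complement over the
diagonal random-effect block), and the σ_u normalizing term.  `REML`
(default) maximizes this criterion over (log λ_s, log λ_g, log σ_u²) by
Nelder–Mead with an explicit unit-scale initial simplex; `fixed` mode uses
user-supplied values and is fully deterministic, which the test-suite uses
for speed.  Curvature from active non-negativity bounds is ignored in the
determinant (the Hessian is evaluated as if all coefficients were free) — a
working approximation that errs on the side of counting constrained
directions as flexible.

**Optimization.**  The inner problem — joint penalized Bernoulli
log-likelihood over (coefficients, random intercepts) — is convex and is
solved by projected Newton with Armijo backtracking.  The active set pins
non-negative coefficients at zero when their gradient points inward; the
Newton step solves a dense p × p system after eliminating the diagonal
random-intercept block.  Tolerance: projected gradient < 1e-8, at most 200
iterations.  Directions the data never touch (e.g. tensor corners with no
observations) receive no gradient and stay at zero, so the fit is
deterministic and independent of record order up to floating-point
summation (~1e-12).  Quasi-separation is detected from extreme fitted
linear predictors and warned about; the penalized fit is still returned.
Convergence failures are flagged on the returned surface, never silent.

**Prediction.**  ED extraction uses population-level predictions (u = 0,
the median patient); a Gauss–Hermite marginal mode (21 nodes) is available
for population-averaged probabilities.  Predictions outside the
scale-feasible region `change ∈ [baseline − max, baseline]` raise a domain
error rather than extrapolate.

Known behaviour: with few repeated binary observations per patient
(3–4 intervals here), the Laplace/REML estimate of σ_u is biased toward
zero — the fitted σ_u on the default synthetic trial is well below the
generating 0.5.  Population-level (u = 0) predictions, and hence all ED
quantities, are insensitive to this; users needing calibrated variance
components should treat σ_u as qualitative.

## ED extraction

`effective_dose` scans a 0.01-resolution grid over `[0, baseline]` and
refines the bracketing pair by bisection to 1e-8; monotonicity guarantees
the crossing is unique.  `P(0, b) ≥ p` returns 0 (the zero-change floor — a
deterioration is never classified as improvement) and
`P(b, b) < p` returns unattainable (`N.A.`), which happens at low baselines
where only a few points of improvement are possible.  Tables report the
continuous ED (2 d.p.), the whole-point ED (ceiling of the continuous
value, with a 1e-6 tolerance so an exact integer crossing is not pushed up
a point — scores move in whole points and the MCID is the *smallest*
adequate difference), and ED50 as percent of baseline with half-up integer
rounding for display (51.85 → 52, 47.62 → 48).  The sample-average row
averages each ED over observation intervals at their own rolling baselines;
per-observation weighting is the default, per-patient averaging is
available, and baseline-0 intervals (no improvement possible, no table row)
are excluded with a logged count.  A `--clinical-display` option renders
unattainable ED50 percents as 100% for clinical reporting while the machine
output keeps `N.A.`.

## Evaluation and comparator

The ED50 rule classifies an interval as meeting the MCID when its change
reaches the continuous ED50 at its baseline; at zero-floor baselines any
non-deterioration counts as met (flagged in the log whenever used).
Intervals with unattainable ED50 are excluded with a logged count.
Sensitivity, specificity, and percent disagreement are reported overall and
per study; by default they are apparent (computed on the fitting records),
matching how such rules are usually reported.

The comparator computes per (scale, study, interval, GRC category) change
summaries (sample SD, n−1) and the crude/standardized difference between
*slightly better* and *about the same*, pooling SDs as
`√((s₁² + s₂²)/2)` — the average-variance convention of standard
descriptive-table software, which reproduces the published PANDA comparator
values exactly (the df-weighted pooled SD does not: it gives 0.66 rather
than 0.64 for the first PHQ-9 stratum).

## Synthetic trial generator

The generator emulates the pooled two-trial design that motivates the
method: a moderate-severity primary-care study (466 patients, PHQ-9
baseline ~N(12.0, 5.8), 3 intervals, 5-level GRC) and a treatment-resistant
study (334 patients, ~N(16.6, 5.7), 4 intervals, 3-level GRC); 800 patients
total, preserving the 653:469 enrolment ratio of the real trials at a size
that keeps the default REML fit under half a minute on one CPU.  Baselines
are rounded and clipped to the scale; scores evolve by
improvement-plus-noise (mean 1.5 points/interval, SD 4 for PHQ-9 — the
scale of published per-interval changes; mean 1.0 for GAD-7, whose reported
changes are smaller).

The response truth is logistic-linear with one interaction,
`logit P = a0 + a1·c + a2·c·b̃ + a3·b̃ + u_i`, with `b̃ = (b − M/2)/(M/2)`
scaled to [−1, 1].  It lies inside the GAMM's function class but admits a
closed-form ED oracle: `c = (logit p − a0 − a3·b̃)/(a1 + a2·b̃)`, floored
at 0 and unattainable above the baseline.  Defaults (PHQ-9: a0 = −3.05,
a1 = 0.50, a2 = 0.10, a3 = −4.15; GAD-7: a0 = −3.10, a1 = 0.60, a2 = 0.10,
a3 = −3.90; σ_u = 0.5) were chosen once so that (i) the ED50 truth spans
≈0 at minimal severity to ≈12 (PHQ-9) / 10 (GAD-7) points at the scale
maximum — the qualitative range the method was designed to reveal — and
(ii) the anchor is informative at every study × interval (Spearman |rho|
0.31–0.58, matching the 0.32–0.52 character of the real trials).  The
ordinal GRC comes from thresholding a latent logistic variable at fixed
cuts with the better/not-better boundary at 0, so the binary collapse is
exactly Bernoulli(sigmoid(η + u)).  An optional baseline-direction sine
"wiggle" makes the surface non-linear in baseline while preserving both
monotonicity in change and the closed-form oracle; it is used for
robustness checks.

What the generator does **not** emulate: treatment-arm effects (the source
design pools arms), study/time covariate effects on the response,
informative dropout, measurement error in scores beyond the
improvement-noise process, and any misspecification of the logistic link.
Passing recovery tests therefore shows the estimator works when its model
class contains the truth; it does not validate the model class against real
response processes.

## Problem sizes and determinism

Default test/acceptance sizes: 800 patients (~2,700 intervals) for recovery
and evaluation runs, ~100 patients for unit-level fits, 2,000 independent
observations for the flat-truth calibration check.  All randomness flows
through explicit seeds (generator default 20210401); fits are deterministic
given data.  The ED grid/bisection search is verified against an exhaustive
0.001-resolution scan on randomized analytic surfaces.

## Limitations

- Confidence intervals for ED curves (e.g. by bootstrap) are not
  implemented.
- Apparent (resubstitution) sensitivity/specificity is the default
  convention; honest split-sample evaluation is available by passing
  held-out records to `compute_metrics`, but no automated splitter is
  provided.
- The integer ED tables of the source trials cannot be regenerated without
  the undeposited individual-level data; validation is structural and
  synthetic-oracle-based.
- σ_u is biased low for short binary panels (see above).
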