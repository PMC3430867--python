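# Methods

This note documents the models, estimation procedures, and design choices
behind `satmodels`, in the spirit of a model-description vignette.

## Scientific setting

The package analyses cued two-choice reaction-time experiments built around
the speed–accuracy tradeoff (SAT): on each trial a cue instructs the
participant to respond either quickly or accurately to a random-dot-motion
stimulus, and each participant completes two pharmacological sessions (an
active drug and a placebo).  The analysis question is whether the drug
shifts the *decision threshold* — the amount of evidence required to commit
to a response — which is the parameter that sequential-sampling models
identify with SAT.  Because threshold effects may exist without mean-RT
effects (and vice versa), the pipeline fits two accumulator models and
tests drug effects on their threshold estimates, alongside conventional
RT/accuracy analyses.

## Drift diffusion model (DDM)

Evidence `X(t)` diffuses from a starting point `z` between absorbing
boundaries at `0` (error) and `a` (correct, for drift `v > 0`), with
infinitesimal SD `s` (the classical scaling constant, fixed at 0.1 and
configurable).  Observed RT is the boundary-crossing time plus a
non-decision time `Ter`.  Across-trial drift variability `eta` (normal) is
supported; start-point variability and contaminant mixtures are out of
scope.

First-passage densities use the standard dual series: an image-method
expansion accurate at small scaled times and an eigenfunction expansion
accurate at large times, with per-time-point truncation counts chosen from
the analytic error bound at target truncation error `1e-7`, switching to
whichever series needs fewer terms.  Tests verify the two branches agree to
`1e-6` in their overlap region and that total first-passage mass is 1 to
`1e-4`.  The `eta` integral is evaluated by 20-node Gauss–Hermite
quadrature.  Defective CDFs, choice probabilities and model-implied
quantiles are obtained by trapezoidal integration of the density on a fine
grid extending to a horizon where the slowest eigenmode
(`pi^2 s^2 / 2a^2 + v^2 / 2s^2`) leaves negligible residual mass.

### Quantile chi-square fitting

For each session, 5 RT quantiles (.1, .3, .5, .7, .9) of correct and error
responses per cue delimit 6 + 6 observed defective bins with masses
`p_correct * (.1,.2,.2,.2,.2,.1)` (and the complementary error vector).
The fitted statistic is `chi2 = sum N_cue (p_obs − p_exp)^2 / p_exp`, with
model bin probabilities floored at `1e-5` to avoid division blow-ups.
Cells with fewer than 5 error responses contribute a single collapsed error
bin rather than noisy error quantiles.

The default free-parameter set is `{a_speed, a_accuracy, Ter_speed,
Ter_accuracy, v}` with optional `eta` (threshold and non-decision time free
per cue; unbiased start `z = a/2`, justified because left/right directions
are collapsed to correct/error coding before fitting).  Minimization is
Nelder–Mead under a logistic box transform (bounds `a ∈ [0.05, 0.40]`,
`Ter ∈ [0.10, 0.60]` s, `v ∈ [0, 0.60]`, `eta ∈ [0, 0.30]`), with seeded
uniform restarts and an iterated "polish" phase that re-seeds the simplex
at the incumbent optimum until the objective stops improving — plain
Nelder–Mead is prone to premature simplex collapse in 5–6 dimensions.
Deadline censoring is ignored in the fitted statistic (non-responses are
excluded upstream); this is a documented approximation.

## Linear ballistic accumulator (LBA)

Two independent accumulators race linearly to a threshold `b`; start
points are uniform on `[0, A]`, rates are drawn per trial from normal
distributions with means `v_correct` (stimulus-matching accumulator) and
`v_error` and common SD `s_drift` (fixed at 1 for identifiability).  The
defective density of the winner is the standard closed form
`f_i(t)(1 − F_j(t))`, normalized by the probability that at least one rate
is positive, `1 − Φ(−v_c/s)Φ(−v_e/s)`; races in which both sampled rates
are negative are treated as non-responses, mirroring the behavioral
exclusion of no-response trials.

A single model is fitted jointly to both sessions by maximum likelihood:
the threshold is free across the four cue-by-session cells and `A`, the two
rate means and `t0` are shared (8 free parameters; alternative sharing is a
config choice).  Log-densities are floored at `1e-10` and floored trials
counted.  The optimizer mirrors the DDM's (box transform, seeded restarts,
iterated polish), with one moment-based start: `t0` anchored near the
fastest RT and each cell's threshold at `v_0 * (median RT − t0) − A_0/2`
for nominal `v_0 = 3`, `A_0 = 1`.  Because the likelihood orders the two
rates only through the data labels, the fit parametrizes
`v_error = ratio * v_correct` with `ratio ∈ [0, 1)`, which enforces the
`v_correct > v_error` convention inside a rectangular box.

## Inference

Mean RT and accuracy (and, downstream, model thresholds arranged as
session × cue) enter 2×2 fully within-subject ANOVAs computed from the
explicit sums-of-squares decomposition, each effect tested against its own
subject-by-effect interaction on (1, n−1) df.  Drug effects per cue are
tested with two-sided paired t-tests and with a default Bayesian one-sample
t-test on drug-minus-placebo difference scores: a Cauchy(0, r) prior on the
standardized effect size with `r = 1`, the convention of the default
Bayesian t-test this mirrors.  The Bayes factor

    BF01 = T_nu(t; 0) / ∫ T_nu(t; δ√n) Cauchy(δ; 0, r) dδ

is computed by adaptive quadrature (relative tolerance `1e-8`) rather than
posterior sampling, so results are exactly reproducible; with equal prior
odds the posterior plausibility of the null is `BF01 / (1 + BF01)`.
Sampling-based implementations of the same test agree only to ~2 decimal
places, which is why the worked-example tolerance is ±0.02.  The
trait-covariate screen computes Pearson correlations between per-subject
drug-effect scores (2 measures × 2 cues) and three trait scores, with a
Bonferroni-corrected per-comparison alpha (`0.05/12 ≈ 0.004` for the
standard family).

## Synthetic-data generator

Raw data for this paradigm are rarely deposited, so the generator is the
package's study stand-in: per session, two blocks of 50 speed-cue, 50
accuracy-cue and 5 dummy (fixation) trials per subject, a 1.0 s response
window after which a trial is a non-response, and feedback labels (the
400 ms "in time" rule affects labels only, never the generative process).
Subject parameters are drawn from population distributions; the speed cue
multiplies the threshold by 0.6 and the drug session by a configurable
factor (1.0 = no effect, the default, matching the null conclusion such a
study design is powered to support).  Trait covariates (BIS ~ N(19, 4),
BAS ~ N(40, 5), Barratt impulsiveness ~ N(62, 10)) attach per subject with
a configurable correlation to the subject's drug-effect deviation.

Default populations — DDM: `a_accuracy ~ N(0.16, 0.03)`,
`Ter ~ N(0.30, 0.03)` s, `v ~ N(0.15, 0.04)`, `eta = 0`, `s = 0.1`;
LBA: `b_accuracy ~ N(1.6, 0.15)`, `A ~ N(0.8, 0.1)`,
`v_c ~ N(3.0, 0.3)`, `v_e ~ N(1.5, 0.2)`, `t0 ~ N(0.25, 0.03)` s,
`s_drift = 1` — chosen once so summaries sit in the task's regime (speed
RTs ≈ 0.45–0.50 s below accuracy RTs ≈ 0.6–0.7 s; accuracy rates in the
70–95% band).  No claim is made that they match any particular unpublished
dataset; what passing tests show is that the *pipeline* recovers what the
generator plants, not that real data follow these distributions.  Real
data also exhibit features the generator omits: sequential dependencies,
fatigue and practice drifts, contaminant RTs, and trait–behavior structure
beyond a single linear correlation.

DDM trials are simulated by Euler–Maruyama steps with a Brownian-bridge
crossing correction — each step accepts an unseen boundary touch with
probability `exp(−2(a−x0)(a−x1)/(s^2 dt))` (and the lower-boundary
analogue) — plus uniform within-step jitter of the crossing time.  This
removes the `O(sqrt(dt))` first-passage bias of the naive scheme, so the
default `dt = 1e-3` s is adequate even for the million-trial oracle
comparisons; recovery experiments use `dt = 2e-4`.  LBA trials are exact
draws from the model.  All generation flows from a single
`numpy.random.SeedSequence`, spawned per subject, making every table
bit-exact regenerable from config + seed (the table metadata records
both).

## Pipeline and reproducibility

`run_behavioral_analysis` executes, in a fixed logged order: preprocessing
(dummy and no-response removal, direction collapsing) → subject exclusions
(accuracy-cue accuracy strictly below 60%, pooled over sessions by
default; per-session assessment and accuracy-over-all-trials are config
options) → cell summary statistics → RT and accuracy ANOVAs → per-session
DDM fits and a joint LBA fit per subject → threshold ANOVAs for both
models → paired and Bayesian t-tests per measure and cue → the trait
correlation screen (skipped and logged when traits are absent or n < 3) →
vincentized group quantiles with model-implied overlays.  Reports carry an
input hash, the config, and all derived seeds; identical inputs and seed
yield byte-identical report bodies.  Floats are rounded to 10 decimals at
serialization so report equality is not hostage to printing noise.

Problem sizes used by the shipped validation suite: Monte-Carlo oracle
comparisons at 10^6 trials; parameter-recovery at 2000 trials per cell
with 8 seeded replicates per model; pipeline determinism on compact
synthetic studies.  These sizes give sampling error comfortably below the
asserted tolerances while keeping the suite quick to run.

## Known limitations

- The DDM variant is deliberately minimal (no start-point variability,
  no `st0` in the fitted set by default, no contaminant mixture); it is a
  quantile-fitting engine for threshold questions, not the full diffusion
  model with every variability component.
- Deadline censoring is ignored in both fitted objectives; with the
  default generator settings the censored mass is a few percent in the
  accuracy cells and the induced threshold bias is well inside the
  recovery tolerances, but heavy censoring regimes would need an explicit
  censored likelihood.
- The chi-square fit inherits the usual fragility of error-quantile bins
  when error counts are low; the collapsed-bin rule mitigates but does not
  remove it.
- Bayes factors are one-sample JZS only; Bayesian ANOVA and other prior
  families are out of scope.
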