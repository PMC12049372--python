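# Methods

## Model and estimand

A two-arm randomized trial with a continuous outcome is modeled per arm as

    Y_Ti = f_T(x_i) + ε_Ti,   ε_Ti ~ N(0, σ²_T),   T ∈ {E, C},

where x_i is the vector of baseline covariates. The two noise variances
are estimated separately and are not assumed equal. The target is the
conditional (per-patient) effect τ(x) = f_E(x) − f_C(x); its plug-in
estimate PITE_i = f̂_E(x_i) − f̂_C(x_i) is computed for **all** trial
patients regardless of assigned arm. The ATE estimate is the mean PITE and
the heterogeneity summary is the sample SD of the PITEs (n−1 denominator;
defined as exactly 0 for a constant vector).

Because randomization makes treatment independent of covariates, the PITE
is an estimate of a causal contrast; its quality is limited entirely by
how well f̂_T approximates f_T.

## Learners

Both built-in learners implement the same contract — `fit` on one arm,
`predict_point`, and `predict_draws` returning an (n_draws × n) matrix of
realizations of the fitted *function*. Draws deliberately exclude the
patient-level noise ε: the effect subtracts fitted functions, not noisy
outcomes, so intervals quantify uncertainty about τ(x), not about an
individual outcome difference. Coverage is accordingly evaluated against
the true τ(x).

**bayes_linear.** Conjugate normal–inverse-gamma linear regression with
intercept. Prior: coefficients ~ N(0, σ²/λ) with λ = 1 (intercept gets a
near-flat λ₀ = 10⁻⁶), σ² ~ InvGamma(a₀ = 0.01, b₀ = 0.01). Continuous
covariates are standardized by default using training-arm moments
(population SD; zero-variance columns pass through with scale 1), which
makes the prior unit-free and predictions exactly invariant to affine
rescaling of any continuous covariate. The posterior is exact and closed
form; when the prior precision matrix is λI the posterior mean coincides
with the ridge solution (XᵀX + λI)⁻¹Xᵀy, which the tests exploit as an
independent linear-algebra oracle. Draws sample σ² ~ InvGamma(a_n, b_n)
and then β | σ² ~ N(μ_n, σ²Λ_n⁻¹) via a Cholesky solve.

**bootstrap_trees.** An ensemble of CART regression trees (scikit-learn),
each fit to a bootstrap resample of the arm; defaults: 200 replicates,
unlimited depth, minimum leaf size 10. Point prediction is the ensemble
mean; draws resample ensemble members, so dispersion reflects resampling
variability of the fitted function. Fitting requires n ≥ 2·min_leaf.

**external_adapter** is a named family that documents the interface a
third-party Bayesian sampler (e.g. a BART implementation) must satisfy;
no sampler is bundled.

Covariate columns are canonicalized to lexicographic order inside the
learners, so all predictions are invariant to input column order.

## Intervals and decisions

Per-patient intervals are equal-tailed empirical quantiles of the PITE
draw column at levels ((1−L)/2, 1−(1−L)/2), with linear (type-7)
interpolation; the default level is L = 0.80. The two arms' draw streams
are independent sub-streams of the analysis seed — nothing couples them,
and no coupling is assumed. A closed interval containing 0 yields
`uncertain`; otherwise the interval's side of zero, combined with the
declared outcome direction (`higher_is_better` / `lower_is_better`),
yields `favors_experimental` or `favors_control`. Widening L can only
grow intervals, so the count of uncertain decisions is monotone in L.

## Permutation test for heterogeneity

Null hypothesis: τ(x) is constant. Treatment labels are permuted
uniformly at random over patients with arm sizes preserved — the standard
randomization null for a two-arm trial — while rows (x, Y) stay fixed.
For each of B permutations both arm models are refit from scratch with
identical hyperparameters (no re-tuning, preserving exchangeability at
linear cost in B), PITEs are recomputed for all patients, and the SD is
recorded. The p-value is (1 + #{s_b ≥ s_obs})/(B + 1): add-one smoothing
guarantees validity and a minimum of 1/(B+1); ties count toward the null
(conservative). Default B = 1000 for single-dataset analyses; simulation
cells use B = 199, which is valid and five times cheaper.

Permutations are defined on rows sorted by patient id and per-permutation
seeds derive deterministically from (master seed, b), so the p-value is
reproducible and independent of input row order. An exhaustive mode
enumerates all C(n, n_E) distinct assignments (bounded, default 10⁵) and
is used to check the Monte-Carlo path against brute-force enumeration at
n = 8.

Note the statistic depends only on point predictions, so the test never
computes function draws.

## Synthetic trials

The generator draws independent standard-normal continuous covariates
(optionally exchangeably correlated via a single ρ knob — an extension
beyond the motivating analysis) and Bernoulli(0.5) binary covariates (by
default the last p//3 columns), assigns treatment completely at random
with fixed arm sizes, and sets Y = f_T(x) + N(0, σ²_T). The control
surface is linear, f_C = bᵀx with b_j = 1/√p (unit-scale systematic
variation at any p); a `nonlinear` baseline adds x₁x₂ + 1{x₁ > 0}. Effect
scenarios:

| scenario        | τ(x)                                   | default parameters    |
|-----------------|----------------------------------------|-----------------------|
| `null`          | τ₀                                     | τ₀ = 0.3              |
| `het_linear`    | τ₀ + γᵀx                               | γ = (0.5) on x₁       |
| `het_strong`    | τ₀ + γᵀx                               | γ = (1, 1) on x₁, x₂  |
| `het_nonlinear` | τ₀ + g·x₁x₂ + h·1{x₁>0}                | g = h = 1             |

Noise defaults to σ_E = σ_C = 1, so effect scales are in noise-SD units:
`het_linear` has true effect SD 0.5 (a moderate, realistic signal),
`het_strong` SD ≈ √2 (clearly detectable at a few hundred patients), and
`het_nonlinear` is constructed so a linear learner is misspecified for
τ while tree ensembles are not. The default trial shape (n = 2910, arms
1766/1144, p = 17) mirrors a pooled ALS trial database analyzed with this
framework; simulation cells use p = 5, a typical covariate count for
operating-characteristic studies that keeps replicated refits cheap
without changing what is being tested.

True per-patient effects and noiseless surfaces are recorded, making
recovery, coverage, and decision-accuracy metrics exact.

What the generator does **not** emulate: real covariate distributions and
correlations of any particular disease population, study-pooling
artifacts, longitudinal outcome construction (the outcome here is a
ready-made scalar, e.g. an already-derived functional-score slope), or
informative missingness (the complete-case filter is exercised on data
missing completely at random). Passing tests therefore demonstrate
correctness of the machinery and its frequentist properties under a
well-specified or deliberately misspecified model — not performance on
any real trial.

## Evaluation harness

`run_simulation` replicates generate → fit → test over a scenario grid:
rejection rate at α (default 0.05), heterogeneity-SD estimate vs truth,
PITE RMSE and correlation with truth, interval coverage, and a 3×2
decision-vs-true-sign confusion table. Replicate failures abort the cell
with a logged diagnostic rather than being skipped. `holdout_accuracy`
reports per-arm RMSE and R² on a stratified held-out split (R² against
the test-arm mean, so a constant prediction scores 0). Decision confusion
counts a zero-true-effect patient as unfavorable only when a clear
decision was made for them (any clear call on a zero effect is an error);
the convention is logged.

Problem sizes used by the test suite and the acceptance script — type-I
error at n = 200 with B = 199 over 400 replicates, power at n = 400 over
200 replicates, coverage at n = 1000 over 40 replicates, recovery at
n = 2000 over 200 replicates, learner comparison at n = 2000 over 100
replicates — are large enough that Monte-Carlo error is small relative to
the property being checked (e.g. 3 binomial SEs of a 5% rate at R = 400
is ±3.3 points). Coverage is summarized as the mean of per-replicate
coverages with an empirical Monte-Carlo SE, because patients within one
replicate share fitted coefficients and are not independent Bernoulli
trials.

## Numerical choices and degenerate inputs

- All randomness flows from explicit integer seeds through
  `numpy.random.SeedSequence` spawning; identical seeds give byte-identical
  outputs end to end.
- A zero-variance outcome is a valid bayes_linear fit (the posterior
  concentrates); a zero-variance covariate is centered and passed through.
- Constant PITE vectors produce exactly zero heterogeneity SD (explicit
  guard against floating-point residue), which makes the all-ties
  permutation p-value exactly 1.
- The quadratic form in the posterior scale b_n is clipped at zero against
  rounding.
- Stratified splitting allocates round(fraction·n_arm) per arm and refuses
  any split that would empty an arm in either part.

## Limitations

- Intervals are credible/resampling intervals for τ(x) under the chosen
  learner; under misspecification (e.g. linear learner on the nonlinear
  scenario) they can undercover and the decisions inherit that error.
- The permutation null assumes exchangeability of labels given covariates;
  with a non-zero constant effect the permuted mixture slightly inflates
  outcome variance, making the test mildly conservative (the type-I
  simulations quantify this).
- No variable selection, variable-importance analysis, or multi-study
  pooling adjustments; hyperparameters are fixed, not tuned.
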