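# pite — predicted individual treatment effects for two-arm trials

Average treatment effects from a randomized trial hide the fact that
patients differ: the same drug can help one patient and harm another.
`pite` implements the *predicted individual treatment effect* (PITE)
approach for a two-arm randomized trial with a continuous outcome. It is
aimed at biostatisticians and methods researchers who want to estimate
per-patient effects, test whether effect heterogeneity is real, and study
the operating characteristics of the whole procedure on synthetic trials
with a known truth.

## The model

Each arm's outcome is modeled as a function of baseline covariates plus
arm-specific noise,

```
Y_Ti = f_T(x_i) + ε_Ti,    ε_Ti ~ N(0, σ²_T),    T ∈ {E, C},
```

with the variances allowed to differ between arms. Fitting `f_E` and `f_C`
separately (a T-learner) and differencing the predictions gives each
patient's predicted individual treatment effect

```
PITE_i = f̂_E(x_i) − f̂_C(x_i).
```

The mean PITE estimates the average treatment effect (ATE). Uncertainty
intervals for each PITE come from draws of the two fitted functions
(independent streams per arm); a patient whose interval excludes zero gets
a *clear* treatment recommendation, the rest stay *uncertain*.

Whether heterogeneity exists at all is tested with a permutation test: the
statistic is the sample SD of the PITEs, and its null distribution is
obtained by shuffling treatment labels (arm sizes preserved), refitting
both models from scratch, and recomputing the SD — by default B = 1000
times, with the add-one p-value `(1 + #{s_b ≥ s_obs}) / (B + 1)`.

Two learners with honest uncertainty are built in: an exact conjugate
Bayesian linear model (normal–inverse-gamma posterior, closed form) and a
bootstrap ensemble of regression trees; any external sampler that emits
function draws (e.g. BART) can be plugged in through the same interface.

## Worked example

```python
from pite import (LearnerSpec, fit_pite, generate_trial, permutation_test,
                  decision_summary)
from pite.synthetic_data import SyntheticTrialConfig

cfg = SyntheticTrialConfig(n=600, arm_sizes=(300, 300), p=5,
                           scenario="het_linear", seed=42)
trial = generate_trial(cfg)          # known truth: τ(x) = 0.3 + 0.5·x1
spec = LearnerSpec()                 # conjugate Bayesian linear learner

test = permutation_test(trial.dataset, spec, B=1000, seed=1)
print(f"observed SD of PITEs = {test.observed_statistic:.3f}, "
      f"p = {test.p_value:.4f}")

_, _, result = fit_pite(trial.dataset, spec, n_draws=2000,
                        interval_level=0.80, seed=2)
print(f"ATE estimate = {result.ate_estimate:.3f}")
for tag, frac in decision_summary(result).items():
    print(f"{tag}: {frac:.1%}")
```

prints

```
observed SD of PITEs = 0.472, p = 0.0010
ATE estimate = 0.312
favors_experimental: 58.5%
favors_control: 12.2%
uncertain: 29.3%
```

The observed SD (0.472) is close to the true effect SD of 0.5; the p-value
is the smallest possible at B = 1000, i.e. strong evidence of
heterogeneity. The ATE recovers the true average effect of 0.3, and at the
80% level about 71% of patients get a clear recommendation while 29%
remain uncertain — even though the *average* effect is positive, 12% of
patients are predicted to do clearly better on control.

The same pipeline is available from the shell (`pite generate`,
`pite fit`, `pite test-het`, `pite evaluate`, `pite simulate`); each run
records its resolved configuration and seed next to its outputs and writes
the ordered-PITE ("waterfall") and permutation-distribution plots.

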