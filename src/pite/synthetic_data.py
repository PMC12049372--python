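"""Synthetic two-arm randomized trials with a known effect surface.

The generator draws baseline covariates (independent standard-normal
continuous columns — optionally exchangeably correlated — and Bernoulli(0.5)
binary columns), assigns treatment completely at random with fixed arm
sizes (or per-patient randomization probability), and produces outcomes

    Y_i = f_{T_i}(x_i) + Normal(0, sigma^2_{T_i}),

with arm-specific (possibly unequal) noise SDs. The control surface f_C is
linear (optionally augmented with an interaction and a threshold term), and
f_E = f_C + tau(x) where tau is the true individual treatment effect:

``null``          tau(x) = tau0 for everyone (no heterogeneity).
``het_linear``    tau(x) = tau0 + gamma . x, default gamma = 0.5 on the
                  first covariate.
``het_strong``    same form, default gamma = 1.0 on the first two
                  covariates (easily detectable heterogeneity).
``het_nonlinear`` tau(x) = tau0 + g_prod * x1 * x2 + g_thr * 1{x1 > 0},
                  using the first two continuous covariates — a surface a
                  linear learner is misspecified for while tree ensembles
                  are not.

Every truth (per-patient tau, noiseless f_C and f_E) is recorded so that
estimator recovery, interval coverage, and decision accuracy can be
measured exactly. Default dimensions follow a pooled ALS trial database of
2,910 patients (1,766 experimental / 1,144 control) with 17 baseline
covariates.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .trial_data import (BINARY, CONTINUOUS, CONTROL, EXPERIMENTAL,
                         HIGHER_IS_BETTER, TrialDataset, write_trial)

SCENARIO_NULL = "null"
SCENARIO_HET_LINEAR = "het_linear"
SCENARIO_HET_STRONG = "het_strong"
SCENARIO_HET_NONLINEAR = "het_nonlinear"
SCENARIOS = (SCENARIO_NULL, SCENARIO_HET_LINEAR, SCENARIO_HET_STRONG,
             SCENARIO_HET_NONLINEAR)

BASELINE_LINEAR = "linear"
BASELINE_NONLINEAR = "nonlinear"

_DEFAULT_GAMMA = {
    SCENARIO_HET_LINEAR: (0.5,),
    SCENARIO_HET_STRONG: (1.0, 1.0),
}


class ConfigError(ValueError):
    """The synthetic-trial configuration is inconsistent."""


@dataclass(frozen=True)
class SyntheticTrialConfig:
    """Data-generating process for one synthetic trial.

    Parameters
    ----------
    n, arm_sizes
        Total patients and (n_E, n_C); alternatively ``arm_sizes`` may be a
        float randomization probability of the experimental arm, in which
        case arm sizes are binomial. Defaults emulate the pooled ALS
        illustration (2910 patients, 1766/1144).
    p, covariate_kinds
        Covariate count and per-column kinds; by default the last p // 3
        columns are binary and the rest continuous standard-normal.
    baseline, baseline_coefs, baseline_intercept
        Control surface. ``linear``: f_C = b0 + b . x with default
        b_j = 1/sqrt(p) (unit-scale systematic variation regardless of p).
        ``nonlinear`` adds x1 * x2 + 1{x1 > 0}.
    scenario, tau0, gamma, gamma_product, gamma_threshold
        True effect surface (see module docstring). ``gamma`` may be
        shorter than p; remaining coefficients are zero.
    noise
        (sigma_E, sigma_C) outcome noise SDs, possibly unequal.
    rho
        Exchangeable correlation among continuous covariates (0 = independent).
    """

    n: int = 2910
    arm_sizes: tuple[int, int] | float = (1766, 1144)
    p: int = 17
    covariate_kinds: tuple[str, ...] | None = None
    baseline: str = BASELINE_LINEAR
    baseline_coefs: tuple[float, ...] | None = None
    baseline_intercept: float = 0.0
    scenario: str = SCENARIO_NULL
    tau0: float = 0.3
    gamma: tuple[float, ...] | None = None
    gamma_product: float = 1.0
    gamma_threshold: float = 1.0
    noise: tuple[float, float] = (1.0, 1.0)
    rho: float = 0.0
    outcome_direction: str = HIGHER_IS_BETTER
    seed: int = 0

    def __post_init__(self) -> None:
        if self.scenario not in SCENARIOS:
            raise ConfigError(f"unknown scenario {self.scenario!r}; "
                              f"expected one of {SCENARIOS}")
        if self.baseline not in (BASELINE_LINEAR, BASELINE_NONLINEAR):
            raise ConfigError(f"unknown baseline {self.baseline!r}")
        if self.n < 1 or self.p < 1:
            raise ConfigError("n and p must be positive")
        if isinstance(self.arm_sizes, tuple):
            n_E, n_C = self.arm_sizes
            if n_E < 1 or n_C < 1 or n_E + n_C != self.n:
                raise ConfigError(
                    f"arm sizes {self.arm_sizes} must be positive and sum "
                    f"to n = {self.n}")
        elif not 0.0 < float(self.arm_sizes) < 1.0:
            raise ConfigError("randomization probability must be in (0, 1)")
        if any(s < 0 for s in self.noise):
            raise ConfigError("noise SDs must be non-negative")
        if not 0.0 <= self.rho < 1.0:
            raise ConfigError("rho must be in [0, 1)")
        if self.covariate_kinds is not None and \
                len(self.covariate_kinds) != self.p:
            raise ConfigError("covariate_kinds length must equal p")

    # -- resolved pieces of the DGP ---------------------------------------
    def resolved_kinds(self) -> tuple[str, ...]:
        if self.covariate_kinds is not None:
            return tuple(self.covariate_kinds)
        n_binary = self.p // 3
        return (CONTINUOUS,) * (self.p - n_binary) + (BINARY,) * n_binary

    def resolved_baseline_coefs(self) -> np.ndarray:
        if self.baseline_coefs is not None:
            b = np.asarray(self.baseline_coefs, dtype=float)
            if b.size != self.p:
                raise ConfigError("baseline_coefs length must equal p")
            return b
        return np.full(self.p, 1.0 / np.sqrt(self.p))

    def resolved_gamma(self) -> np.ndarray:
        g = np.zeros(self.p)
        if self.scenario in (SCENARIO_HET_LINEAR, SCENARIO_HET_STRONG):
            raw = self.gamma if self.gamma is not None \
                else _DEFAULT_GAMMA[self.scenario]
            raw = np.asarray(raw, dtype=float)
            if raw.size > self.p:
                raise ConfigError("gamma longer than p")
            g[:raw.size] = raw
        return g

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["covariate_kinds"] = (list(self.covariate_kinds)
                                if self.covariate_kinds else None)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticTrialConfig":
        d = dict(d)
        for key in ("arm_sizes", "noise", "gamma", "baseline_coefs",
                    "covariate_kinds"):
            if key in d and isinstance(d[key], list):
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass
class SyntheticTrial:
    """A generated trial plus its data-generating truths."""

    dataset: TrialDataset
    true_ite: np.ndarray    # tau(x_i)
    true_fC: np.ndarray     # noiseless control surface
    true_fE: np.ndarray     # noiseless experimental surface
    config: SyntheticTrialConfig


def _tau(config: SyntheticTrialConfig, X: np.ndarray) -> np.ndarray:
    if config.scenario == SCENARIO_NULL:
        return np.full(X.shape[0], config.tau0)
    if config.scenario in (SCENARIO_HET_LINEAR, SCENARIO_HET_STRONG):
        return config.tau0 + X @ config.resolved_gamma()
    # het_nonlinear: product + threshold on the first two covariates
    if config.p < 2:
        raise ConfigError("het_nonlinear needs p >= 2")
    return (config.tau0
            + config.gamma_product * X[:, 0] * X[:, 1]
            + config.gamma_threshold * (X[:, 0] > 0.0).astype(float))


def _baseline(config: SyntheticTrialConfig, X: np.ndarray) -> np.ndarray:
    f = config.baseline_intercept + X @ config.resolved_baseline_coefs()
    if config.baseline == BASELINE_NONLINEAR:
        if config.p < 2:
            raise ConfigError("nonlinear baseline needs p >= 2")
        f = f + X[:, 0] * X[:, 1] + (X[:, 0] > 0.0).astype(float)
    return f


def generate_trial(config: SyntheticTrialConfig) -> SyntheticTrial:
    """Draw one trial from the configured process; fully reproducible."""
    rng = np.random.default_rng(config.seed)
    kinds = config.resolved_kinds()
    n, p = config.n, config.p

    X = np.empty((n, p))
    cont = np.array([k == CONTINUOUS for k in kinds])
    n_cont = int(cont.sum())
    if n_cont:
        Z = rng.standard_normal((n, n_cont))
        if config.rho > 0:
            shared = rng.standard_normal((n, 1))
            Z = np.sqrt(config.rho) * shared + np.sqrt(1 - config.rho) * Z
        X[:, cont] = Z
    if n_cont < p:
        X[:, ~cont] = rng.binomial(1, 0.5, size=(n, p - n_cont))

    if isinstance(config.arm_sizes, tuple):
        n_E, n_C = config.arm_sizes
        labels = np.array([EXPERIMENTAL] * n_E + [CONTROL] * n_C,
                          dtype=object)
        treatment = rng.permutation(labels)
    else:
        pr = float(config.arm_sizes)
        treatment = np.where(rng.random(n) < pr, EXPERIMENTAL,
                             CONTROL).astype(object)

    fC = _baseline(config, X)
    tau = _tau(config, X)
    fE = fC + tau
    is_E = treatment == EXPERIMENTAL
    sigma = np.where(is_E, config.noise[0], config.noise[1])
    y = np.where(is_E, fE, fC) + sigma * rng.standard_normal(n)

    width = len(str(n))
    ids = np.array([f"P{i + 1:0{width}d}" for i in range(n)])
    covariates = pd.DataFrame(X, columns=[f"x{j + 1}" for j in range(p)])
    dataset = TrialDataset(
        patient_ids=ids, treatment=treatment, outcome=y,
        covariates=covariates,
        covariate_kinds={f"x{j + 1}": kinds[j] for j in range(p)},
        outcome_direction=config.outcome_direction,
    )
    return SyntheticTrial(dataset=dataset, true_ite=tau, true_fC=fC,
                          true_fE=fE, config=config)


def true_heterogeneity_sd(trial: SyntheticTrial) -> float:
    """Sample SD (n-1) of the true per-patient effects — the estimand the
    heterogeneity statistic targets. Zero under the null scenario."""
    ite = trial.true_ite
    if ite.size < 2 or ite.max() == ite.min():
        return 0.0
    return float(np.std(ite, ddof=1))


def write_synthetic(trial: SyntheticTrial, outdir: str | Path,
                    float_format: str = "%.12g") -> dict[str, Path]:
    """Write trial CSV + schema, the truths CSV, and the config YAML."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "trial": outdir / "trial.csv",
        "schema": outdir / "schema.yaml",
        "truths": outdir / "truths.csv",
        "config": outdir / "config.yaml",
    }
    schema = write_trial(trial.dataset, paths["trial"],
                         float_format=float_format)
    schema.to_file(paths["schema"])
    pd.DataFrame({
        "patient_id": trial.dataset.patient_ids,
        "true_ite": trial.true_ite,
        "true_fC": trial.true_fC,
        "true_fE": trial.true_fE,
    }).to_csv(paths["truths"], index=False, float_format=float_format,
              encoding="utf-8")
    paths["config"].write_text(
        yaml.safe_dump(trial.config.to_dict(), sort_keys=False),
        encoding="utf-8")
    return paths
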