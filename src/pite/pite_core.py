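"""Per-patient predicted individual treatment effects (PITEs).

The PITE of patient i is the difference between that patient's predicted
outcome under the experimental and the control condition,

    PITE_i = f_hat_E(x_i) - f_hat_C(x_i),

computed from two arm-specific outcome models fit to a randomized trial.
Uncertainty intervals come from draws of the two fitted functions (with
independent draw streams per arm), and each patient is classified as
clearly favoring one treatment — interval excluding zero — or uncertain.
The mean PITE estimates the average treatment effect (ATE); the sample SD
of the PITEs summarizes treatment-effect heterogeneity.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .learners import FittedOutcomeModel, LearnerSpec, fit_outcome_model
from .trial_data import (CONTROL, EXPERIMENTAL, HIGHER_IS_BETTER,
                         LOWER_IS_BETTER, OUTCOME_DIRECTIONS, TrialDataset)

FAVORS_EXPERIMENTAL = "favors_experimental"
FAVORS_CONTROL = "favors_control"
UNCERTAIN = "uncertain"
DECISIONS = (FAVORS_EXPERIMENTAL, FAVORS_CONTROL, UNCERTAIN)


class ContractError(ValueError):
    """The two arm models disagree on the covariate column set."""


class IntervalError(ValueError):
    """Intervals were requested with too few draws."""


def classify_decision(interval: tuple[float, float],
                      outcome_direction: str) -> str:
    """Treatment decision from one patient's uncertainty interval.

    ``uncertain`` when the closed interval contains zero; otherwise the
    interval lies entirely on one side, and whether that side is beneficial
    depends on the declared outcome direction.
    """
    lower, upper = interval
    if lower > upper:
        raise ValueError(f"interval lower bound exceeds upper: {interval}")
    if outcome_direction not in OUTCOME_DIRECTIONS:
        raise ValueError(f"unknown outcome_direction {outcome_direction!r}")
    if lower <= 0.0 <= upper:
        return UNCERTAIN
    positive = lower > 0.0
    if outcome_direction == HIGHER_IS_BETTER:
        return FAVORS_EXPERIMENTAL if positive else FAVORS_CONTROL
    return FAVORS_CONTROL if positive else FAVORS_EXPERIMENTAL


@dataclass
class PITEResult:
    """Per-patient treatment-effect predictions and their summaries.

    ``pite_draws`` has shape (n_draws, n); ``intervals`` are equal-tailed
    empirical quantiles of each patient's draw column at the requested
    level; ``decisions`` classify each interval against zero.
    ``heterogeneity_sd`` is the n-1 sample SD of the point PITEs (0.0 when
    n < 2).
    """

    patient_ids: np.ndarray
    pite_point: np.ndarray
    pite_draws: np.ndarray | None
    interval_level: float | None
    lower: np.ndarray | None
    upper: np.ndarray | None
    decisions: np.ndarray | None
    ate_estimate: float
    heterogeneity_sd: float
    outcome_direction: str = HIGHER_IS_BETTER

    @property
    def n(self) -> int:
        return self.pite_point.size

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"patient_id": self.patient_ids,
                           "pite_point": self.pite_point})
        if self.lower is not None:
            df["lower"] = self.lower
            df["upper"] = self.upper
            df["decision"] = self.decisions
        return df

    def write_csv(self, path: str | Path,
                  float_format: str = "%.12g") -> None:
        self.to_frame().to_csv(path, index=False, float_format=float_format,
                               encoding="utf-8")

    def summary(self) -> dict:
        out = {
            "n": int(self.n),
            "ate_estimate": float(self.ate_estimate),
            "heterogeneity_sd": float(self.heterogeneity_sd),
            "interval_level": self.interval_level,
            "outcome_direction": self.outcome_direction,
        }
        if self.decisions is not None:
            out["decision_proportions"] = decision_summary(self)
        return out

    def write_summary_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.summary(), indent=2) + "\n",
                              encoding="utf-8")


def compute_pite(
    model_E: FittedOutcomeModel,
    model_C: FittedOutcomeModel,
    X,
    n_draws: int = 2000,
    interval_level: float | None = 0.80,
    seed: int = 0,
    outcome_direction: str = HIGHER_IS_BETTER,
    patient_ids: np.ndarray | None = None,
) -> PITEResult:
    """PITEs, uncertainty intervals, and decisions for every row of X.

    The two arm models must share a covariate column set. Draw streams for
    the two arms are independent sub-streams of ``seed``. Set
    ``interval_level=None`` (or ``n_draws=0``) to skip draws and intervals
    and return point estimates only.
    """
    if set(model_E.feature_names_) != set(model_C.feature_names_):
        raise ContractError(
            "arm models were trained on different covariate sets: "
            f"{model_E.feature_names_} vs {model_C.feature_names_}")
    point = model_E.predict_point(X) - model_C.predict_point(X)
    n = point.size
    if patient_ids is None:
        patient_ids = np.arange(n)
    patient_ids = np.asarray(patient_ids)

    draws = lower = upper = decisions = None
    if interval_level is not None and n_draws > 0:
        if not 0.0 < interval_level < 1.0:
            raise IntervalError("interval_level must be in (0, 1), got "
                                f"{interval_level}")
        if n_draws < 2:
            raise IntervalError(
                f"intervals need n_draws >= 2, got {n_draws}")
        seed_E, seed_C = _arm_seeds(seed)
        draws = (model_E.predict_draws(X, n_draws, seed_E)
                 - model_C.predict_draws(X, n_draws, seed_C))
        alpha = (1.0 - interval_level) / 2.0
        lower, upper = np.quantile(draws, [alpha, 1.0 - alpha], axis=0)
        decisions = np.array(
            [classify_decision((lo, hi), outcome_direction)
             for lo, hi in zip(lower, upper)], dtype=object)

    return PITEResult(
        patient_ids=patient_ids,
        pite_point=point,
        pite_draws=draws,
        interval_level=interval_level if draws is not None else None,
        lower=lower,
        upper=upper,
        decisions=decisions,
        ate_estimate=float(point.mean()),
        heterogeneity_sd=(float(np.std(point, ddof=1))
                          if n > 1 and point.max() > point.min() else 0.0),
        outcome_direction=outcome_direction,
    )


def _arm_seeds(seed: int) -> tuple[int, int]:
    """Independent per-arm draw seeds derived from a master seed."""
    ss = np.random.SeedSequence(seed)
    a, b = ss.spawn(2)
    return (int(a.generate_state(1)[0] % (2**31 - 1)),
            int(b.generate_state(1)[0] % (2**31 - 1)))


def fit_pite(
    data: TrialDataset,
    spec: LearnerSpec,
    n_draws: int = 2000,
    interval_level: float | None = 0.80,
    seed: int = 0,
) -> tuple[FittedOutcomeModel, FittedOutcomeModel, PITEResult]:
    """End-to-end PITE analysis of a trial.

    Fits one model per arm (with seeds derived from ``seed``) and computes
    PITEs for **all** trial patients regardless of assigned arm.
    """
    data.require_both_arms()
    fit_E, fit_C, draw_seed = _pipeline_seeds(seed)
    model_E = fit_outcome_model(data.arm(EXPERIMENTAL), spec, seed=fit_E)
    model_C = fit_outcome_model(data.arm(CONTROL), spec, seed=fit_C)
    result = compute_pite(model_E, model_C, data.covariates,
                          n_draws=n_draws, interval_level=interval_level,
                          seed=draw_seed,
                          outcome_direction=data.outcome_direction,
                          patient_ids=data.patient_ids)
    return model_E, model_C, result


def _pipeline_seeds(seed: int) -> tuple[int, int, int]:
    ss = np.random.SeedSequence(seed)
    return tuple(int(c.generate_state(1)[0] % (2**31 - 1))
                 for c in ss.spawn(3))


def decision_summary(result: PITEResult) -> dict[str, float]:
    """Proportion of patients in each decision class (sums to 1)."""
    if result.decisions is None:
        raise ValueError("result carries no decisions; compute intervals "
                         "first")
    n = result.n
    return {tag: float(np.sum(result.decisions == tag)) / n
            for tag in DECISIONS}


def plot_waterfall(result: PITEResult, ax=None, max_patients: int = 100,
                   seed: int = 0):
    """Ordered-PITE plot: each patient's point estimate with its interval,
    sorted by effect size, with a horizontal line at the ATE.

    When the trial has more than ``max_patients`` patients, a random subset
    of that size is displayed (seeded).
    """
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(8, 4.5))
    idx = np.arange(result.n)
    if result.n > max_patients:
        idx = np.random.default_rng(seed).choice(result.n, max_patients,
                                                 replace=False)
    order = idx[np.argsort(result.pite_point[idx])]
    xs = np.arange(order.size)
    if result.lower is not None:
        ax.vlines(xs, result.lower[order], result.upper[order],
                  color="0.7", lw=1.0,
                  label=f"{int(round(result.interval_level * 100))}% interval")
    ax.plot(xs, result.pite_point[order], "k.", ms=4, label="PITE")
    ax.axhline(result.ate_estimate, color="tab:blue", lw=1.2, label="ATE")
    ax.axhline(0.0, color="0.3", lw=0.8, ls=":")
    ax.set_xlabel("patients (ordered by predicted effect)")
    ax.set_ylabel("predicted individual treatment effect")
    ax.legend(loc="best", fontsize=8)
    return ax
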