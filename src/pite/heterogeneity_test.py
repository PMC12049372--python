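"""Permutation test for treatment-effect heterogeneity.

The null hypothesis is that the individual treatment effect is the same for
every patient. Under that null the treatment labels are exchangeable with
respect to any label-dependent structure in the effects, so the reference
distribution of a heterogeneity statistic can be obtained by randomly
reassigning arm labels (preserving arm sizes), refitting both arm models
from scratch with identical hyperparameters, recomputing PITEs for all
patients, and recording the statistic.

The statistic is the sample standard deviation of the predicted individual
treatment effects. The p-value uses the add-one convention

    p = (1 + #{b : s_b >= s_obs}) / (B + 1),

which is a valid permutation p-value (never below 1/(B+1)) and counts ties
conservatively. An exhaustive mode enumerates all C(n, n_E) distinct label
assignments instead of sampling; it is intended for small-n oracle checks.

Permutations are defined on rows sorted by patient id, so the p-value does
not depend on the row order of the input for a fixed seed.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from itertools import combinations
from pathlib import Path

import numpy as np

from .learners import (CONTINUOUS, LearnerSpec, _fit_predict_point_arrays)
from .trial_data import EXPERIMENTAL, TrialDataset


class StatisticError(ValueError):
    """The PITE vector is too short for a spread statistic."""


class ConfigurationError(ValueError):
    """Exhaustive enumeration was requested beyond the configured bound."""


def heterogeneity_statistic(pite_point) -> float:
    """Sample SD (n-1 denominator) of a vector of PITEs."""
    v = np.asarray(pite_point, dtype=float)
    if v.size < 2:
        raise StatisticError(
            f"heterogeneity statistic needs >= 2 values, got {v.size}")
    if v.max() == v.min():  # constant vector: exactly zero spread
        return 0.0
    return float(np.std(v, ddof=1))


@dataclass
class PermutationTestResult:
    """Observed statistic, permutation replicates, and add-one p-value."""

    observed_statistic: float
    permutation_statistics: np.ndarray
    n_permutations: int
    p_value: float
    seed: int
    learner_spec: LearnerSpec
    exhaustive: bool = False

    def to_dict(self) -> dict:
        return {
            "observed_statistic": float(self.observed_statistic),
            "n_permutations": int(self.n_permutations),
            "p_value": float(self.p_value),
            "seed": int(self.seed),
            "exhaustive": bool(self.exhaustive),
            "learner_spec": self.learner_spec.to_dict(),
        }

    def write_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n",
                              encoding="utf-8")


def permutation_test(
    data: TrialDataset,
    spec: LearnerSpec,
    B: int = 1000,
    seed: int = 0,
    exhaustive: bool = False,
    max_exhaustive: int = 100_000,
) -> PermutationTestResult:
    """Permutation test of no treatment-effect heterogeneity.

    Parameters
    ----------
    data
        Two-arm trial; both arms must be non-empty.
    spec
        Learner configuration, reused unchanged (no re-tuning) for the
        observed fit and for every permutation refit.
    B
        Number of Monte-Carlo permutations (default 1000). Ignored in
        exhaustive mode, where B becomes the number of distinct label
        assignments C(n, n_E).
    exhaustive
        Enumerate all distinct assignments of n_E experimental labels to
        patients. Raises :class:`ConfigurationError` when C(n, n_E)
        exceeds ``max_exhaustive``.
    """
    data.require_both_arms()
    if B < 1:
        raise ValueError("B must be >= 1")

    # canonical ordering: rows sorted by patient id, columns sorted by name
    order = np.argsort(data.patient_ids, kind="stable")
    data = data.take(order)
    names = sorted(data.columns)
    X = data.covariates[names].to_numpy(dtype=float)
    y = data.outcome
    continuous = np.array([data.covariate_kinds[c] == CONTINUOUS
                           for c in names])
    labels = data.treatment == EXPERIMENTAL
    n, n_E = labels.size, int(labels.sum())

    master = np.random.SeedSequence(seed)

    def statistic(mask: np.ndarray, fit_seed: int) -> float:
        pred_E = _fit_predict_point_arrays(X, y, mask, continuous, spec,
                                           fit_seed)
        pred_C = _fit_predict_point_arrays(X, y, ~mask, continuous, spec,
                                           fit_seed + 1)
        return heterogeneity_statistic(pred_E - pred_C)

    obs_seed = int(master.generate_state(1)[0] % (2**31 - 2))
    observed = statistic(labels, obs_seed)

    if exhaustive:
        total = math.comb(n, n_E)
        if total > max_exhaustive:
            raise ConfigurationError(
                f"exhaustive mode would enumerate C({n}, {n_E}) = {total} "
                f"assignments, above the bound {max_exhaustive}")
        stats = np.empty(total)
        for b, chosen in enumerate(combinations(range(n), n_E)):
            mask = np.zeros(n, dtype=bool)
            mask[list(chosen)] = True
            stats[b] = statistic(mask, _perm_seed(master, b))
        B_eff = total
    else:
        children = master.spawn(B)
        stats = np.empty(B)
        for b, child in enumerate(children):
            rng = np.random.default_rng(child)
            mask = np.zeros(n, dtype=bool)
            mask[rng.choice(n, n_E, replace=False)] = True
            stats[b] = statistic(
                mask, int(child.generate_state(2)[1] % (2**31 - 2)))
        B_eff = B

    p_value = (1.0 + float(np.sum(stats >= observed))) / (B_eff + 1.0)
    return PermutationTestResult(
        observed_statistic=observed,
        permutation_statistics=stats,
        n_permutations=B_eff,
        p_value=p_value,
        seed=seed,
        learner_spec=spec,
        exhaustive=exhaustive,
    )


def _perm_seed(master: np.random.SeedSequence, b: int) -> int:
    """Deterministic per-permutation fit seed from (master seed, b)."""
    return int(np.random.SeedSequence((master.entropy, b))
               .generate_state(1)[0] % (2**31 - 2))


def plot_permutation_distribution(result: PermutationTestResult, ax=None,
                                  bins: int = 30):
    """Histogram of the permutation statistics with the observed SD marked
    as a vertical red line."""
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    ax.hist(result.permutation_statistics, bins=bins, color="0.75",
            edgecolor="0.4")
    ax.axvline(result.observed_statistic, color="red", lw=1.5,
               label=f"observed SD (p = {result.p_value:.4g})")
    ax.set_xlabel("SD of PITEs under permuted treatment labels")
    ax.set_ylabel("count")
    ax.legend(loc="best", fontsize=8)
    return ax
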