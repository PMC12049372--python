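"""Operating characteristics of the PITE pipeline on synthetic truth.

`run_simulation` replicates the full analysis — generate a trial, fit both
arm models, compute PITEs (optionally with intervals), run the permutation
heterogeneity test — over a grid of data-generating configurations, and
aggregates: rejection rate at a stated alpha (type-I error under the null
scenario, power under heterogeneous ones), the heterogeneity-SD estimate
against its true value, PITE recovery (RMSE and correlation with the true
per-patient effect), interval coverage of the true effect, and a confusion
table of treatment decisions against the sign of the true effect.

`holdout_accuracy` measures per-arm predictive accuracy (RMSE, R^2) on a
held-out part of a real or synthetic trial — the sample-splitting check a
PITE analysis should report before its predictions are trusted.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .heterogeneity_test import permutation_test
from .learners import LearnerSpec, fit_outcome_model
from .pite_core import (DECISIONS, FAVORS_CONTROL, FAVORS_EXPERIMENTAL,
                        PITEResult, UNCERTAIN, fit_pite)
from .synthetic_data import (SyntheticTrialConfig, generate_trial,
                             true_heterogeneity_sd)
from .trial_data import (ARMS, HIGHER_IS_BETTER, LOWER_IS_BETTER,
                         TrialDataset)

logger = logging.getLogger(__name__)

FAVORABLE = "favorable"      # true effect benefits the experimental arm
UNFAVORABLE = "unfavorable"


class ContractError(ValueError):
    pass


def decision_confusion(result: PITEResult, true_ite) -> pd.DataFrame:
    """3x2 cross-tabulation: decision tag vs sign of the true effect.

    Columns: ``favorable`` (the true effect benefits the experimental arm
    under the result's outcome direction) and ``unfavorable``. Patients
    with exactly zero true effect are counted as unfavorable when a clear
    decision was made for them (any clear call on a zero effect is a
    mistake) and as favorable otherwise; the convention is logged.
    """
    if result.decisions is None:
        raise ContractError("result carries no decisions")
    true_ite = np.asarray(true_ite, dtype=float)
    if true_ite.size != result.n:
        raise ContractError(
            f"true_ite length {true_ite.size} != n = {result.n}")
    if result.outcome_direction == HIGHER_IS_BETTER:
        favorable = true_ite > 0
    else:
        favorable = true_ite < 0
    zero = true_ite == 0
    clear = result.decisions != UNCERTAIN
    if (zero & clear).any():
        logger.info("counting %d zero-true-effect patients with clear "
                    "decisions as unfavorable", int((zero & clear).sum()))
    favorable = favorable | (zero & ~clear)
    table = pd.DataFrame(0, index=list(DECISIONS),
                         columns=[FAVORABLE, UNFAVORABLE])
    for tag in DECISIONS:
        in_tag = result.decisions == tag
        table.loc[tag, FAVORABLE] = int((in_tag & favorable).sum())
        table.loc[tag, UNFAVORABLE] = int((in_tag & ~favorable).sum())
    return table


def holdout_accuracy(train: TrialDataset, test: TrialDataset,
                     spec: LearnerSpec, seed: int = 0) -> dict:
    """Per-arm RMSE and R^2 of point predictions on held-out outcomes.

    R^2 is computed against the test-arm outcome mean, so a constant
    prediction at that mean scores exactly 0.
    """
    train.require_both_arms()
    test.require_both_arms()
    ss = np.random.SeedSequence(seed)
    seeds = [int(c.generate_state(1)[0] % (2**31 - 1)) for c in ss.spawn(2)]
    out = {}
    for arm, s in zip(ARMS, seeds):
        model = fit_outcome_model(train.arm(arm), spec, seed=s)
        part = test.arm(arm)
        pred = model.predict_point(part.covariates)
        resid = part.outcome - pred
        rmse = float(np.sqrt(np.mean(resid ** 2)))
        ss_tot = float(np.sum((part.outcome - part.outcome.mean()) ** 2))
        r2 = 1.0 - float(np.sum(resid ** 2)) / ss_tot if ss_tot > 0 else \
            float("nan")
        out[arm] = {"rmse": rmse, "r2": r2, "n_test": part.n}
    return out


@dataclass
class SimulationReport:
    """Aggregated operating characteristics, one cell per configuration."""

    cells: list[dict]
    replicates: int
    alpha: float
    seed: int

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for cell in self.cells:
            row = {k: v for k, v in cell.items()
                   if k not in ("config", "confusion")}
            conf = cell.get("confusion")
            if conf is not None:
                for tag in DECISIONS:
                    for col in (FAVORABLE, UNFAVORABLE):
                        row[f"confusion_{tag}_{col}"] = int(
                            conf.loc[tag, col])
            rows.append(row)
        return pd.DataFrame(rows)

    def write_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False, encoding="utf-8")

    def write_json(self, path) -> None:
        payload = {
            "replicates": self.replicates,
            "alpha": self.alpha,
            "seed": self.seed,
            "cells": json.loads(
                self.to_frame().to_json(orient="records")),
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=2)
            fh.write("\n")


def run_simulation(
    grid: list[SyntheticTrialConfig],
    spec: LearnerSpec,
    B: int = 199,
    R: int = 100,
    alpha: float = 0.05,
    seed: int = 0,
    n_draws: int = 0,
    interval_level: float = 0.80,
) -> SimulationReport:
    """Replicate the full pipeline over a configuration grid.

    For each cell, R independent trials are generated (seeds derived from
    ``seed``); each is analyzed end to end. ``B`` is the permutation count
    per replicate; set ``B=0`` to skip the heterogeneity test, and leave
    ``n_draws=0`` to skip intervals (coverage and confusion then reported
    as NaN/None). A replicate that raises aborts its cell with a logged
    diagnostic — cells are never silently skipped.
    """
    if R < 1:
        raise ValueError("R must be >= 1")
    if not grid:
        raise ValueError("grid must be non-empty")
    master = np.random.SeedSequence(seed)
    cell_seqs = master.spawn(len(grid))
    cells = []
    for config, cell_seq in zip(grid, cell_seqs):
        rep_seqs = cell_seq.spawn(R)
        rejects, sd_est, sd_true, rmse, corr, coverage = \
            [], [], [], [], [], []
        confusion = None
        for r, rep_seq in enumerate(rep_seqs):
            s_gen, s_fit, s_perm = (
                int(c.generate_state(1)[0] % (2**31 - 1))
                for c in rep_seq.spawn(3))
            try:
                trial = generate_trial(
                    dataclasses.replace(config, seed=s_gen))
                _, _, result = fit_pite(
                    trial.dataset, spec, n_draws=n_draws,
                    interval_level=interval_level if n_draws else None,
                    seed=s_fit)
                if B:
                    test = permutation_test(trial.dataset, spec, B=B,
                                            seed=s_perm)
                    rejects.append(test.p_value <= alpha)
                sd_est.append(result.heterogeneity_sd)
                sd_true.append(true_heterogeneity_sd(trial))
                err = result.pite_point - trial.true_ite
                rmse.append(float(np.sqrt(np.mean(err ** 2))))
                spread = np.std(trial.true_ite) * np.std(result.pite_point)
                corr.append(
                    float(np.corrcoef(result.pite_point,
                                      trial.true_ite)[0, 1])
                    if spread > 0 else float("nan"))
                if result.lower is not None:
                    coverage.append(float(np.mean(
                        (result.lower <= trial.true_ite)
                        & (trial.true_ite <= result.upper))))
                    conf = decision_confusion(result, trial.true_ite)
                    confusion = conf if confusion is None else \
                        confusion + conf
            except Exception:
                logger.exception(
                    "replicate %d of scenario %r failed; aborting cell",
                    r, config.scenario)
                raise
        cell = {
            "config": config,
            "scenario": config.scenario,
            "n": config.n,
            "rejection_rate": float(np.mean(rejects)) if rejects else
            float("nan"),
            "mean_sd_estimate": float(np.mean(sd_est)),
            "median_sd_estimate": float(np.median(sd_est)),
            "mean_true_sd": float(np.mean(sd_true)),
            "mean_rmse": float(np.mean(rmse)),
            "median_correlation": float(np.median(corr)),
            "mean_coverage": float(np.mean(coverage)) if coverage else
            float("nan"),
            "confusion": confusion,
        }
        cells.append(cell)
    return SimulationReport(cells=cells, replicates=R, alpha=alpha,
                            seed=seed)
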