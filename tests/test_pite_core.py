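import inspect

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pite import (LearnerSpec, classify_decision, compute_pite,
                  decision_summary, fit_outcome_model, fit_pite)
from pite.pite_core import (ContractError, IntervalError, PITEResult,
                            FAVORS_CONTROL, FAVORS_EXPERIMENTAL, UNCERTAIN)

from conftest import make_dataset

FLAT = LearnerSpec(hyperparameters={"lam": 1e-10},
                   standardize_covariates=False)


def linear_arm_model(beta, n=60, seed=0, arm="E"):
    """Fit a near-flat-prior linear model to noiseless beta-generated data,
    so the posterior mean equals beta to numerical precision."""
    data = make_dataset(n=n, p=len(beta) - 1, seed=seed)
    X = data.covariates.to_numpy()
    data.outcome = beta[0] + X @ np.asarray(beta[1:])
    return fit_outcome_model(data.arm(arm), FLAT)


class TestComputePite:
    def test_identical_models_give_zero_effects(self):
        model = linear_arm_model([1.0, 2.0, -1.0])
        X = make_dataset(n=10, p=2, seed=1).covariates
        res = compute_pite(model, model, X, n_draws=0, interval_level=None)
        np.testing.assert_allclose(res.pite_point, 0.0, atol=1e-12)
        assert res.heterogeneity_sd == 0.0

    def test_linear_arms_match_hand_computed_difference(self):
        """With known posterior-mean coefficients beta_E and beta_C the
        PITE is (beta_E - beta_C) . (1, x) — checked on 4 patients by
        direct arithmetic."""
        beta_E = np.array([1.0, 2.0, -1.0])
        beta_C = np.array([0.5, 1.0, 0.5])
        model_E = linear_arm_model(beta_E, seed=2, arm="E")
        model_C = linear_arm_model(beta_C, seed=3, arm="C")
        X = pd.DataFrame({"x1": [0.0, 1.0, -1.0, 2.0],
                          "x2": [1.0, 0.0, 2.0, -1.0]})
        res = compute_pite(model_E, model_C, X, n_draws=0,
                           interval_level=None)
        D = np.hstack([np.ones((4, 1)), X.to_numpy()])
        np.testing.assert_allclose(res.pite_point, D @ (beta_E - beta_C),
                                   atol=1e-6)

    def test_default_interval_level_is_80_percent(self):
        assert inspect.signature(compute_pite) \
            .parameters["interval_level"].default == 0.80

    def test_ate_equals_difference_of_mean_predictions(self, small_trial,
                                                       linear_spec):
        _, _, res = fit_pite(small_trial.dataset, linear_spec, n_draws=0,
                             interval_level=None, seed=5)
        mE = fit_outcome_model(small_trial.dataset.arm("E"), linear_spec)
        mC = fit_outcome_model(small_trial.dataset.arm("C"), linear_spec)
        X = small_trial.dataset.covariates
        expected = mE.predict_point(X).mean() - mC.predict_point(X).mean()
        assert res.ate_estimate == pytest.approx(expected, rel=1e-12)

    def test_widening_interval_never_reduces_uncertain_count(
            self, small_trial, linear_spec):
        _, _, res80 = fit_pite(small_trial.dataset, linear_spec,
                               n_draws=500, interval_level=0.80, seed=6)
        _, _, res95 = fit_pite(small_trial.dataset, linear_spec,
                               n_draws=500, interval_level=0.95, seed=6)
        assert np.sum(res95.decisions == UNCERTAIN) >= \
            np.sum(res80.decisions == UNCERTAIN)

    def test_row_shuffle_equivariance(self, small_trial, linear_spec):
        data = small_trial.dataset
        mE = fit_outcome_model(data.arm("E"), linear_spec)
        mC = fit_outcome_model(data.arm("C"), linear_spec)
        X = data.covariates
        res = compute_pite(mE, mC, X, n_draws=400, seed=8)
        perm = np.random.default_rng(0).permutation(data.n)
        res_p = compute_pite(mE, mC, X.iloc[perm], n_draws=400, seed=8)
        np.testing.assert_allclose(res_p.pite_point, res.pite_point[perm])
        np.testing.assert_allclose(res_p.lower, res.lower[perm])
        np.testing.assert_allclose(res_p.upper, res.upper[perm])

    def test_mismatched_covariate_sets_rejected(self):
        m1 = linear_arm_model([0.0, 1.0])
        m2 = linear_arm_model([0.0, 1.0, 1.0])
        with pytest.raises(ContractError):
            compute_pite(m1, m2, pd.DataFrame({"x1": [0.0]}))

    def test_single_draw_with_interval_rejected(self):
        m = linear_arm_model([0.0, 1.0])
        with pytest.raises(IntervalError):
            compute_pite(m, m, pd.DataFrame({"x1": [0.0]}), n_draws=1)


class TestClassifyDecision:
    @pytest.mark.parametrize("interval,direction,expected", [
        ((-1.0, 1.0), "higher_is_better", UNCERTAIN),
        ((0.2, 0.9), "higher_is_better", FAVORS_EXPERIMENTAL),
        ((0.2, 0.9), "lower_is_better", FAVORS_CONTROL),
        ((-0.9, -0.2), "higher_is_better", FAVORS_CONTROL),
        ((-0.9, -0.2), "lower_is_better", FAVORS_EXPERIMENTAL),
        ((0.0, 0.5), "higher_is_better", UNCERTAIN),  # closed interval
    ])
    def test_interval_classification(self, interval, direction, expected):
        assert classify_decision(interval, direction) == expected

    def test_inverted_interval_rejected(self):
        with pytest.raises(ValueError):
            classify_decision((1.0, -1.0), "higher_is_better")


def result_from_intervals(intervals, direction="higher_is_better"):
    lower = np.array([i[0] for i in intervals], float)
    upper = np.array([i[1] for i in intervals], float)
    point = (lower + upper) / 2
    decisions = np.array([classify_decision(i, direction)
                          for i in intervals], dtype=object)
    return PITEResult(
        patient_ids=np.arange(len(intervals)), pite_point=point,
        pite_draws=None, interval_level=0.8, lower=lower, upper=upper,
        decisions=decisions, ate_estimate=float(point.mean()),
        heterogeneity_sd=(float(np.std(point, ddof=1))
                          if point.size > 1 else 0.0),
        outcome_direction=direction)


class TestDecisionSummary:
    def test_all_intervals_containing_zero_are_uncertain(self):
        res = result_from_intervals([(-1, 1), (-2, 0.5), (0, 3)])
        assert decision_summary(res) == {
            FAVORS_EXPERIMENTAL: 0.0, FAVORS_CONTROL: 0.0, UNCERTAIN: 1.0}

    def test_hand_classified_four_patient_fixture(self):
        res = result_from_intervals([(1, 2), (-2, -1), (-1, 1), (0.5, 3)])
        assert decision_summary(res) == {
            FAVORS_EXPERIMENTAL: 0.5, FAVORS_CONTROL: 0.25, UNCERTAIN: 0.25}

    @given(st.lists(
        st.tuples(st.floats(-5, 5), st.floats(0, 5)).map(
            lambda t: (t[0], t[0] + t[1])),
        min_size=1, max_size=30))
    @settings(derandomize=True, max_examples=50)
    def test_proportions_always_sum_to_one(self, intervals):
        res = result_from_intervals(intervals)
        assert sum(decision_summary(res).values()) == pytest.approx(1.0)


class TestExports:
    def test_csv_and_summary_outputs(self, tmp_path, small_trial,
                                     linear_spec):
        _, _, res = fit_pite(small_trial.dataset, linear_spec,
                             n_draws=300, seed=9)
        res.write_csv(tmp_path / "pite.csv")
        df = pd.read_csv(tmp_path / "pite.csv")
        assert list(df.columns) == ["patient_id", "pite_point", "lower",
                                    "upper", "decision"]
        assert len(df) == small_trial.dataset.n
        summary = res.summary()
        assert sum(summary["decision_proportions"].values()) == \
            pytest.approx(1.0)

    def test_waterfall_plot_smoke(self, small_trial, linear_spec):
        _, _, res = fit_pite(small_trial.dataset, linear_spec,
                             n_draws=100, seed=10)
        ax = __import__("pite").plot_waterfall(res, max_patients=50)
        assert ax is not None
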