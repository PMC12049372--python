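import numpy as np
import pandas as pd
import pytest

from pite import LearnerSpec, fit_outcome_model
from pite.learners import (FitError, PredictionError,
                           _bayes_linear_coef_draws)

from conftest import make_dataset


def fit_arm(data, spec, arm="E", seed=0):
    return fit_outcome_model(data.arm(arm), spec, seed=seed)


def linear_fixture(beta, n=50, p=None, seed=0, arm="E"):
    """Noiseless y = beta0 + beta[1:] . x data restricted to one arm."""
    p = p if p is not None else len(beta) - 1
    data = make_dataset(n=n, p=p, seed=seed)
    X = data.covariates.to_numpy()
    data.outcome = beta[0] + X @ np.asarray(beta[1:])
    return data.arm(arm)


class TestBayesLinear:
    def test_constant_outcome_predicts_the_constant(self):
        data = make_dataset(n=30, p=2, seed=1).arm("E")
        data.outcome = np.full(data.n, 5.0)
        model = fit_outcome_model(data, LearnerSpec())
        pred = model.predict_point(data.covariates)
        np.testing.assert_allclose(pred, 5.0, atol=1e-3)

    def test_posterior_mean_matches_ridge_oracle(self):
        """With a common prior precision lam on every design column, the
        conjugate posterior mean is the ridge solution
        (X'X + lam I)^-1 X'y — checked by direct linear algebra."""
        rng = np.random.default_rng(42)
        data = make_dataset(n=20, p=2, seed=42).arm("E")  # 10 x 2 arm
        lam = 0.7
        spec = LearnerSpec(hyperparameters={"lam": lam, "lam_intercept": lam},
                           standardize_covariates=False)
        model = fit_outcome_model(data, spec)
        D = np.hstack([np.ones((data.n, 1)),
                       data.covariates[model.feature_names_].to_numpy()])
        oracle = np.linalg.solve(D.T @ D + lam * np.eye(3),
                                 D.T @ data.outcome)
        np.testing.assert_allclose(model.posterior_mean_, oracle, rtol=1e-8)

    def test_known_coefficients_give_linear_predictions(self):
        # essentially flat prior on noiseless y = 1 + 2x  ->  f(3) = 7
        arm = linear_fixture([1.0, 2.0], n=40, seed=3)
        spec = LearnerSpec(hyperparameters={"lam": 1e-10},
                           standardize_covariates=False)
        model = fit_outcome_model(arm, spec)
        pred = model.predict_point(pd.DataFrame({"x1": [3.0]}))
        assert pred[0] == pytest.approx(7.0, abs=1e-6)

    def test_zero_variance_outcome_is_a_valid_fit(self):
        data = make_dataset(n=12, p=1, seed=4).arm("E")
        data.outcome = np.zeros(data.n)
        model = fit_outcome_model(data, LearnerSpec())
        assert np.isfinite(model.predict_point(data.covariates)).all()

    def test_needs_two_observations(self):
        data = make_dataset(n=8, p=1, seed=5).arm("E").take([0])
        with pytest.raises(FitError):
            fit_outcome_model(data, LearnerSpec())


class TestDraws:
    def test_draw_mean_matches_closed_form_posterior_mean(self):
        """Row means of 20,000 exact posterior draws sit within 3 Monte
        Carlo standard errors of the analytic posterior-mean predictor."""
        data = make_dataset(n=60, p=3, seed=6).arm("E")
        model = fit_outcome_model(data, LearnerSpec())
        X = data.covariates
        draws = model.predict_draws(X, n_draws=20_000, seed=123)
        point = model.predict_point(X)
        mc_se = draws.std(axis=0, ddof=1) / np.sqrt(draws.shape[0])
        assert np.all(np.abs(draws.mean(axis=0) - point) < 3 * mc_se + 1e-12)

    def test_single_draw_shape(self):
        data = make_dataset(n=20, p=2, seed=7).arm("E")
        model = fit_outcome_model(data, LearnerSpec())
        assert model.predict_draws(data.covariates, 1, seed=0).shape == \
            (1, data.n)

    def test_degenerate_posterior_draws_collapse_to_point(self):
        data = make_dataset(n=20, p=2, seed=8).arm("E")
        model = fit_outcome_model(data, LearnerSpec())
        # zero-posterior-covariance fixture: huge precision, vanishing noise
        model._state.chol = np.eye(3) * 1e9
        model._state.b_n = 1e-30
        draws = model.predict_draws(data.covariates, 50, seed=1)
        np.testing.assert_allclose(
            draws, np.tile(model.predict_point(data.covariates), (50, 1)),
            atol=1e-8)

    def test_empirical_coefficient_covariance_matches_closed_form(self):
        """50,000 coefficient draws reproduce the analytic marginal
        posterior covariance entrywise within Monte-Carlo tolerance."""
        data = make_dataset(n=40, p=2, seed=9).arm("E")
        model = fit_outcome_model(data, LearnerSpec())
        draws = _bayes_linear_coef_draws(model._state, 50_000,
                                         np.random.default_rng(7))
        emp = np.cov(draws.T)
        closed = model.posterior_covariance_
        scale = np.sqrt(np.outer(np.diag(closed), np.diag(closed)))
        assert np.all(np.abs(emp - closed) < 0.05 * scale)


class TestBootstrapTrees:
    def test_point_prediction_is_ensemble_mean(self, trees_spec):
        data = make_dataset(n=40, p=2, seed=10).arm("E")
        model = fit_outcome_model(data, trees_spec, seed=3)
        from pite.learners import _trees_member_matrix
        members = _trees_member_matrix(
            model._state, data.covariates[model.feature_names_].to_numpy())
        np.testing.assert_allclose(model.predict_point(data.covariates),
                                   members.mean(axis=0))

    def test_refit_with_same_seed_is_identical(self, trees_spec):
        data = make_dataset(n=40, p=2, seed=11).arm("E")
        m1 = fit_outcome_model(data, trees_spec, seed=5)
        m2 = fit_outcome_model(data, trees_spec, seed=5)
        np.testing.assert_array_equal(m1.predict_point(data.covariates),
                                      m2.predict_point(data.covariates))
        np.testing.assert_array_equal(
            m1.predict_draws(data.covariates, 7, seed=2),
            m2.predict_draws(data.covariates, 7, seed=2))

    def test_minimum_sample_size_enforced(self):
        spec = LearnerSpec(family="bootstrap_trees",
                           hyperparameters={"min_leaf": 10})
        data = make_dataset(n=30, p=1, seed=12).arm("E")  # 15 < 20
        with pytest.raises(FitError):
            fit_outcome_model(data, spec)


class TestInvariances:
    @pytest.mark.parametrize("family,hp", [
        ("bayes_linear", {}),
        ("bootstrap_trees", {"n_replicates": 20, "min_leaf": 3}),
    ])
    def test_column_order_invariance(self, family, hp):
        data = make_dataset(n=40, p=3, seed=13).arm("E")
        spec = LearnerSpec(family=family, hyperparameters=hp)
        model = fit_outcome_model(data, spec, seed=1)
        shuffled = data.take(np.arange(data.n))
        shuffled.covariates = shuffled.covariates[["x3", "x1", "x2"]]
        model2 = fit_outcome_model(shuffled, spec, seed=1)
        np.testing.assert_allclose(
            model.predict_point(data.covariates),
            model2.predict_point(data.covariates[["x2", "x3", "x1"]]),
            rtol=1e-10)

    def test_affine_rescaling_invariance_with_standardization(self):
        data = make_dataset(n=40, p=2, seed=14).arm("E")
        spec = LearnerSpec(standardize_covariates=True)
        model = fit_outcome_model(data, spec)
        rescaled = data.take(np.arange(data.n))
        rescaled.covariates = data.covariates.copy()
        rescaled.covariates["x1"] = 100.0 * data.covariates["x1"] - 7.0
        model2 = fit_outcome_model(rescaled, spec)
        np.testing.assert_allclose(
            model.predict_point(data.covariates),
            model2.predict_point(rescaled.covariates), rtol=1e-9)

    def test_prediction_column_mismatch_rejected(self):
        data = make_dataset(n=20, p=2, seed=15).arm("E")
        model = fit_outcome_model(data, LearnerSpec())
        with pytest.raises(PredictionError):
            model.predict_point(pd.DataFrame({"x1": [0.0], "zz": [1.0]}))


class TestLearnerSpec:
    def test_nonpositive_hyperparameters_rejected(self):
        with pytest.raises(ValueError):
            LearnerSpec(hyperparameters={"lam": 0.0})
        with pytest.raises(ValueError):
            LearnerSpec(family="bootstrap_trees",
                        hyperparameters={"n_replicates": 0})

    def test_serialization_round_trip(self):
        spec = LearnerSpec(family="bootstrap_trees",
                           hyperparameters={"min_leaf": 4},
                           standardize_covariates=False)
        assert LearnerSpec.from_dict(spec.to_dict()) == spec

    def test_external_adapter_states_its_contract(self):
        data = make_dataset(n=20, p=1, seed=16).arm("E")
        with pytest.raises(NotImplementedError, match="predict_draws"):
            fit_outcome_model(data,
                              LearnerSpec(family="external_adapter"))

    def test_mixed_arms_rejected(self):
        data = make_dataset(n=20, p=1, seed=17)
        with pytest.raises(FitError, match="one arm"):
            fit_outcome_model(data, LearnerSpec())
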