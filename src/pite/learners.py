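"""Arm-level outcome models with honest predictive uncertainty.

Each treatment arm of a trial gets its own fitted regression of the outcome
on baseline covariates, Y = f_T(x) + eps with eps ~ N(0, sigma^2_T) and
arm-specific noise variance. Two reference learners are built in:

``bayes_linear``
    Exact conjugate Bayesian linear regression (normal--inverse-gamma prior:
    zero-mean normal on coefficients with shared prior precision ``lam``, a
    much flatter prior on the intercept, inverse-gamma(a0, b0) on the noise
    variance). Point predictions are the posterior-mean linear predictor;
    prediction draws are exact posterior draws of the coefficient vector
    applied to the design. Defaults (lam=1, a0=b0=0.01) are weakly
    informative once covariates are standardized.

``bootstrap_trees``
    An ensemble of regression trees fit to bootstrap resamples of the arm.
    Point predictions are the ensemble mean; draws are per-replicate
    ensemble-member predictions, so draw dispersion reflects resampling
    uncertainty in the fitted function.

Draws represent uncertainty in the fitted function f_T(x) only — the
patient-level noise eps is deliberately excluded, because the individual
treatment effect subtracts fitted functions, not noisy outcomes.

A third family tag, ``external_adapter``, names the contract third-party
samplers (e.g. BART implementations) must meet: ``fit`` on one arm's rows,
``predict_point`` returning one value per row of X, and ``predict_draws``
returning an (n_draws, n_rows) matrix of function realizations.

Covariate columns are canonicalized to lexicographic order internally, so
predictions are invariant to the column order of the input.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from sklearn.tree import DecisionTreeRegressor

from .trial_data import BINARY, CONTINUOUS, TrialDataset

BAYES_LINEAR = "bayes_linear"
BOOTSTRAP_TREES = "bootstrap_trees"
EXTERNAL_ADAPTER = "external_adapter"
FAMILIES = (BAYES_LINEAR, BOOTSTRAP_TREES, EXTERNAL_ADAPTER)

_DEFAULT_HYPERPARAMETERS: dict[str, dict[str, float | int | None]] = {
    BAYES_LINEAR: {
        "lam": 1.0,            # prior precision on covariate coefficients
        "lam_intercept": 1e-6,  # near-flat prior on the intercept
        "a0": 0.01,            # inverse-gamma shape on sigma^2
        "b0": 0.01,            # inverse-gamma scale on sigma^2
    },
    BOOTSTRAP_TREES: {
        "n_replicates": 200,
        "max_depth": None,
        "min_leaf": 10,
    },
    EXTERNAL_ADAPTER: {},
}


class FitError(ValueError):
    """The arm subset is too small (or otherwise unfit) for this learner."""


class PredictionError(ValueError):
    """Prediction covariates do not match the training column set."""


@dataclass(frozen=True)
class LearnerSpec:
    """Configuration of an arm-level outcome learner.

    ``hyperparameters`` are family-specific; unspecified ones take the
    documented defaults. ``standardize_covariates`` (default True) centers
    and scales continuous covariates using training-arm moments, which makes
    the bayes_linear prior unit-free and its predictions exactly invariant
    to affine rescaling of any continuous covariate.
    """

    family: str = BAYES_LINEAR
    hyperparameters: Mapping[str, float | int | None] = field(
        default_factory=dict)
    standardize_covariates: bool = True

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown learner family {self.family!r}; "
                             f"expected one of {FAMILIES}")
        hp = self.resolved_hyperparameters()
        unknown = set(self.hyperparameters) - set(
            _DEFAULT_HYPERPARAMETERS[self.family])
        if unknown:
            raise ValueError(
                f"unknown hyperparameters for {self.family}: {sorted(unknown)}")
        if self.family == BAYES_LINEAR:
            for key in ("lam", "lam_intercept", "a0", "b0"):
                if not hp[key] > 0:
                    raise ValueError(f"{key} must be strictly positive")
        elif self.family == BOOTSTRAP_TREES:
            if int(hp["n_replicates"]) < 1:
                raise ValueError("n_replicates must be >= 1")
            if int(hp["min_leaf"]) < 1:
                raise ValueError("min_leaf must be >= 1")
            if hp["max_depth"] is not None and int(hp["max_depth"]) < 1:
                raise ValueError("max_depth must be >= 1 or None")

    def resolved_hyperparameters(self) -> dict:
        hp = dict(_DEFAULT_HYPERPARAMETERS[self.family])
        hp.update(self.hyperparameters)
        return hp

    def to_dict(self) -> dict:
        return {
            "family": self.family,
            "hyperparameters": dict(self.hyperparameters),
            "standardize_covariates": self.standardize_covariates,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "LearnerSpec":
        return cls(
            family=d.get("family", BAYES_LINEAR),
            hyperparameters=dict(d.get("hyperparameters", {})),
            standardize_covariates=bool(d.get("standardize_covariates", True)),
        )


# ---------------------------------------------------------------------------
# Array-level cores. These operate on plain float matrices in canonical
# column order; the model classes add column bookkeeping on top. The
# permutation test calls the cores directly, which keeps refitting both arms
# hundreds of times per dataset cheap.
# ---------------------------------------------------------------------------

def _standardizer(X: np.ndarray, continuous: np.ndarray):
    """Training-arm location/scale for continuous columns (identity for
    binary ones). Population (ddof=0) moments; zero-variance columns get
    scale 1 so they pass through unchanged after centering."""
    mu = np.zeros(X.shape[1])
    sd = np.ones(X.shape[1])
    if continuous.any():
        mu[continuous] = X[:, continuous].mean(axis=0)
        s = X[:, continuous].std(axis=0)
        sd[continuous] = np.where(s > 0, s, 1.0)
    return mu, sd


def _design(X: np.ndarray, mu: np.ndarray, sd: np.ndarray) -> np.ndarray:
    Z = (X - mu) / sd
    return np.hstack([np.ones((Z.shape[0], 1)), Z])


@dataclass
class _BayesLinearState:
    mu: np.ndarray          # standardizer location
    sd: np.ndarray          # standardizer scale
    post_mean: np.ndarray   # posterior mean of (intercept, coefs)
    chol: np.ndarray        # lower Cholesky factor of posterior precision
    a_n: float
    b_n: float


def _fit_bayes_linear(X: np.ndarray, y: np.ndarray, continuous: np.ndarray,
                      hp: Mapping, standardize: bool) -> _BayesLinearState:
    n, p = X.shape
    if n < 2:
        raise FitError(f"bayes_linear needs n >= 2, got n = {n}")
    if standardize:
        mu, sd = _standardizer(X, continuous)
    else:
        mu, sd = np.zeros(p), np.ones(p)
    D = _design(X, mu, sd)
    prior_prec = np.full(p + 1, float(hp["lam"]))
    prior_prec[0] = float(hp["lam_intercept"])
    precision = D.T @ D + np.diag(prior_prec)
    chol = np.linalg.cholesky(precision)
    # posterior mean: precision^{-1} D^T y via two triangular solves
    rhs = D.T @ y
    post_mean = np.linalg.solve(chol.T, np.linalg.solve(chol, rhs))
    a_n = float(hp["a0"]) + n / 2.0
    quad = float(y @ y - post_mean @ (precision @ post_mean))
    b_n = float(hp["b0"]) + 0.5 * max(quad, 0.0)
    return _BayesLinearState(mu=mu, sd=sd, post_mean=post_mean, chol=chol,
                             a_n=a_n, b_n=b_n)


def _bayes_linear_point(state: _BayesLinearState, X: np.ndarray) -> np.ndarray:
    return _design(X, state.mu, state.sd) @ state.post_mean


def _bayes_linear_coef_draws(state: _BayesLinearState, n_draws: int,
                             rng: np.random.Generator) -> np.ndarray:
    """Exact posterior draws of (intercept, coefficients).

    sigma^2 ~ InvGamma(a_n, b_n), then beta | sigma^2 ~ N(mean,
    sigma^2 * precision^{-1}).
    """
    d = state.post_mean.size
    sigma2 = state.b_n / rng.gamma(state.a_n, 1.0, size=n_draws)
    Z = rng.standard_normal((d, n_draws))
    W = np.linalg.solve(state.chol.T, Z)            # cov(W) = precision^{-1}
    return state.post_mean[None, :] + (np.sqrt(sigma2)[None, :] * W).T


@dataclass
class _TreesState:
    mu: np.ndarray
    sd: np.ndarray
    trees: list
    train_mse: float


def _fit_bootstrap_trees(X: np.ndarray, y: np.ndarray, continuous: np.ndarray,
                         hp: Mapping, standardize: bool,
                         seed: int) -> _TreesState:
    n = X.shape[0]
    min_leaf = int(hp["min_leaf"])
    if n < 2 * min_leaf:
        raise FitError(
            f"bootstrap_trees needs n >= 2 * min_leaf = {2 * min_leaf}, "
            f"got n = {n}")
    if standardize:
        mu, sd = _standardizer(X, continuous)
    else:
        mu, sd = np.zeros(X.shape[1]), np.ones(X.shape[1])
    Z = (X - mu) / sd
    rng = np.random.default_rng(seed)
    max_depth = hp["max_depth"]
    trees = []
    for _ in range(int(hp["n_replicates"])):
        idx = rng.integers(0, n, size=n)
        tree = DecisionTreeRegressor(
            max_depth=None if max_depth is None else int(max_depth),
            min_samples_leaf=min_leaf,
            random_state=int(rng.integers(2**31 - 1)),
        )
        tree.fit(Z[idx], y[idx])
        trees.append(tree)
    state = _TreesState(mu=mu, sd=sd, trees=trees, train_mse=0.0)
    state.train_mse = float(np.mean((_trees_point(state, X) - y) ** 2))
    return state


def _trees_member_matrix(state: _TreesState, X: np.ndarray) -> np.ndarray:
    Z = (X - state.mu) / state.sd
    return np.stack([t.predict(Z) for t in state.trees])


def _trees_point(state: _TreesState, X: np.ndarray) -> np.ndarray:
    return _trees_member_matrix(state, X).mean(axis=0)


# ---------------------------------------------------------------------------
# Public model objects
# ---------------------------------------------------------------------------

class FittedOutcomeModel:
    """A fitted arm-level outcome model f_T(.) with predictive uncertainty.

    Attributes
    ----------
    arm : {"E", "C"}
    spec : LearnerSpec
    feature_names_ : list[str]
        Canonical (lexicographic) training column order.
    noise_variance_estimate : float
        Estimate of the arm-specific noise variance sigma^2_T (posterior
        mean for bayes_linear; training MSE of the ensemble mean for
        bootstrap_trees).
    """

    def __init__(self, arm: str, spec: LearnerSpec,
                 feature_names: list[str], continuous: np.ndarray,
                 state, n: int, seed: int) -> None:
        self.arm = arm
        self.spec = spec
        self.feature_names_ = feature_names
        self._continuous = continuous
        self._state = state
        self.n_train = n
        self.p = len(feature_names)
        self.fit_seed = seed
        if spec.family == BAYES_LINEAR:
            a_n, b_n = state.a_n, state.b_n
            self.noise_variance_estimate = b_n / (a_n - 1.0) if a_n > 1.0 \
                else b_n / a_n
        else:
            self.noise_variance_estimate = state.train_mse

    # -- bayes_linear introspection (used by oracle tests) -----------------
    @property
    def posterior_mean_(self) -> np.ndarray:
        """(intercept, coefficients) posterior mean, bayes_linear only."""
        self._require(BAYES_LINEAR)
        return self._state.post_mean.copy()

    @property
    def posterior_covariance_(self) -> np.ndarray:
        """Marginal posterior covariance of (intercept, coefficients):
        E[sigma^2] * precision^{-1}."""
        self._require(BAYES_LINEAR)
        L = self._state.chol
        inv = np.linalg.solve(L.T, np.linalg.solve(L, np.eye(L.shape[0])))
        return self.noise_variance_estimate * inv

    def _require(self, family: str) -> None:
        if self.spec.family != family:
            raise AttributeError(f"attribute only defined for {family} models")

    # -- prediction --------------------------------------------------------
    def _matrix(self, X) -> np.ndarray:
        if isinstance(X, pd.DataFrame):
            missing = set(self.feature_names_) - set(X.columns)
            extra = set(X.columns) - set(self.feature_names_)
            if missing or extra:
                raise PredictionError(
                    f"covariate columns do not match training set "
                    f"(missing {sorted(missing)}, unexpected {sorted(extra)})")
            return X[self.feature_names_].to_numpy(dtype=float)
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.p:
            raise PredictionError(
                f"expected a 2-d matrix with {self.p} columns "
                f"(canonical order {self.feature_names_})")
        return X

    def predict_point(self, X) -> np.ndarray:
        """Point prediction f_hat_T(x) for each row of X."""
        M = self._matrix(X)
        if self.spec.family == BAYES_LINEAR:
            return _bayes_linear_point(self._state, M)
        return _trees_point(self._state, M)

    def predict_draws(self, X, n_draws: int, seed: int) -> np.ndarray:
        """(n_draws, n_rows) matrix of realizations of f_hat_T(x).

        bayes_linear: exact posterior coefficient draws applied to the
        design (no noise term). bootstrap_trees: ensemble members resampled
        with replacement.
        """
        if n_draws < 1:
            raise ValueError("n_draws must be >= 1")
        M = self._matrix(X)
        rng = np.random.default_rng(seed)
        if self.spec.family == BAYES_LINEAR:
            B = _bayes_linear_coef_draws(self._state, n_draws, rng)
            D = _design(M, self._state.mu, self._state.sd)
            return B @ D.T
        members = _trees_member_matrix(self._state, M)
        pick = rng.integers(0, members.shape[0], size=n_draws)
        return members[pick]


def fit_outcome_model(data: TrialDataset, spec: LearnerSpec,
                      seed: int = 0) -> FittedOutcomeModel:
    """Fit an outcome model to one arm's rows of a trial.

    ``data`` must be restricted to a single arm (e.g. ``data.arm("E")``).
    Deterministic given ``seed``.
    """
    arms = set(data.treatment.tolist())
    if len(arms) != 1:
        raise FitError("fit_outcome_model expects data restricted to one "
                       f"arm, got arms {sorted(arms)}")
    if spec.family == EXTERNAL_ADAPTER:
        raise NotImplementedError(
            "external_adapter names the contract third-party samplers must "
            "meet (fit / predict_point / predict_draws with an "
            "(n_draws, n_rows) function-draw matrix); no sampler is bundled")
    names = sorted(data.columns)
    X = data.covariates[names].to_numpy(dtype=float)
    continuous = np.array([data.covariate_kinds[c] == CONTINUOUS
                           for c in names])
    hp = spec.resolved_hyperparameters()
    if spec.family == BAYES_LINEAR:
        state = _fit_bayes_linear(X, data.outcome, continuous, hp,
                                  spec.standardize_covariates)
    else:
        state = _fit_bootstrap_trees(X, data.outcome, continuous, hp,
                                     spec.standardize_covariates, seed)
    return FittedOutcomeModel(arm=arms.pop(), spec=spec, feature_names=names,
                              continuous=continuous, state=state,
                              n=data.n, seed=seed)


def predict_point(model: FittedOutcomeModel, X) -> np.ndarray:
    return model.predict_point(X)


def predict_draws(model: FittedOutcomeModel, X, n_draws: int,
                  seed: int) -> np.ndarray:
    return model.predict_draws(X, n_draws, seed)


# ---------------------------------------------------------------------------
# Fast label-refit path used by the permutation test
# ---------------------------------------------------------------------------

def _fit_predict_point_arrays(X: np.ndarray, y: np.ndarray,
                              mask: np.ndarray, continuous: np.ndarray,
                              spec: LearnerSpec, seed: int) -> np.ndarray:
    """Fit one arm (rows where ``mask``) on raw arrays and predict all rows.

    Bypasses DataFrame plumbing; used when both arms must be refit for each
    of many permuted label vectors. Columns are assumed already canonical.
    """
    hp = spec.resolved_hyperparameters()
    if spec.family == BAYES_LINEAR:
        state = _fit_bayes_linear(X[mask], y[mask], continuous, hp,
                                  spec.standardize_covariates)
        return _bayes_linear_point(state, X)
    state = _fit_bootstrap_trees(X[mask], y[mask], continuous, hp,
                                 spec.standardize_covariates, seed)
    return _trees_point(state, X)
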