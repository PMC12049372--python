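import matplotlib

matplotlib.use("Agg")

import numpy as np
import pandas as pd
import pytest

from pite import LearnerSpec, TrialDataset, generate_trial
from pite.synthetic_data import SyntheticTrialConfig


@pytest.fixture
def linear_spec():
    return LearnerSpec()


@pytest.fixture
def trees_spec():
    return LearnerSpec(family="bootstrap_trees",
                       hyperparameters={"n_replicates": 30, "min_leaf": 5})


@pytest.fixture
def small_trial():
    """An 80-patient het_linear trial with 3 covariates."""
    cfg = SyntheticTrialConfig(n=80, arm_sizes=(40, 40), p=3,
                               scenario="het_linear", seed=7)
    return generate_trial(cfg)


@pytest.fixture
def tiny_trial():
    """An 8-patient (4/4) trial for exhaustive permutation checks."""
    cfg = SyntheticTrialConfig(n=8, arm_sizes=(4, 4), p=2,
                               scenario="null", seed=11)
    return generate_trial(cfg).dataset


def make_dataset(n=20, p=2, seed=0, outcome_direction="higher_is_better"):
    """Small hand-rollable dataset with both arms."""
    rng = np.random.default_rng(seed)
    X = pd.DataFrame(rng.standard_normal((n, p)),
                     columns=[f"x{j + 1}" for j in range(p)])
    return TrialDataset(
        patient_ids=np.array([f"P{i:03d}" for i in range(n)]),
        treatment=np.array(["E", "C"] * (n // 2), dtype=object),
        outcome=rng.standard_normal(n),
        covariates=X,
        outcome_direction=outcome_direction,
    )
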