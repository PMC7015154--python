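import numpy as np
import pytest

import mixglearn as mg
from mixglearn.superlearner import LearnerSpec


@pytest.fixture(scope="session")
def linear_cohort():
    """n=449 cohort from the linear-effects preset (Hg -0.15, PFOA -0.14)."""
    return mg.generate_cohort(449, seed=101, preset="table3_linear")


@pytest.fixture(scope="session")
def linear_table(linear_cohort):
    return linear_cohort.to_frame()


@pytest.fixture(scope="session")
def linear_dataset(linear_table):
    return mg.build_analysis_dataset(linear_table, "bnt_cued", "maternal")


@pytest.fixture(scope="session")
def noiseless_cohort():
    """Same linear DGP but with zero residual noise, for exact oracles."""
    _, _, dgp = mg.make_preset("table3_linear")
    dgp.noise_sd = 0.0
    dgp.beta_cov = {}
    return mg.generate_cohort(449, seed=202, preset="table3_linear", dgp=dgp)


@pytest.fixture(scope="session")
def noiseless_dataset(noiseless_cohort):
    return mg.build_analysis_dataset(
        noiseless_cohort.to_frame(), "bnt_cued", "maternal"
    )


@pytest.fixture(scope="session")
def glm_fit(noiseless_dataset):
    """GLM-only ensemble on the noiseless linear cohort."""
    return mg.fit_superlearner(
        [LearnerSpec("glm")], noiseless_dataset, k=10, seed=7
    )


@pytest.fixture(scope="session")
def glm_fit_noisy(linear_dataset):
    return mg.fit_superlearner([LearnerSpec("glm")], linear_dataset, k=10, seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
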