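import numpy as np
import pytest

from tchase.cohort import NoiseModel, default_design, default_truth, generate_cohort
from tchase.preprocess import derive_observables


@pytest.fixture(scope="session")
def design():
    return default_design()


@pytest.fixture(scope="session")
def zero_noise():
    return NoiseModel(count_cv=0.0, fraction_logit_sd=0.0)


@pytest.fixture(scope="session")
def ki67_truth_quiet(zero_noise):
    """Full-model ground truth, noiseless generator."""
    return default_truth("ki67", noise=zero_noise)


@pytest.fixture(scope="session")
def freq_truth_quiet(zero_noise):
    return default_truth("frequency", noise=zero_noise)


@pytest.fixture(scope="session")
def counts_truth_quiet(zero_noise):
    return default_truth("counts", noise=zero_noise)


@pytest.fixture(scope="session")
def quiet_obs_cd4(ki67_truth_quiet, design):
    """Zero-noise full-model cohort, CD4 pooled observables."""
    cohort = generate_cohort(ki67_truth_quiet, design, seed=1)
    obs = derive_observables(cohort)
    return obs[obs["lineage"] == "CD4"].reset_index(drop=True)


@pytest.fixture(scope="session")
def noisy_obs_cd4(design):
    cohort = generate_cohort(default_truth("ki67"), design, seed=7)
    obs = derive_observables(cohort)
    return obs[obs["lineage"] == "CD4"].reset_index(drop=True)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
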