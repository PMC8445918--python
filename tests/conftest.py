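"""Shared fixtures: the synthetic truth, noise-free data, and tiny ensembles."""

import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from tamres.fitting import assemble_observations
from tamres.model import ModelParameters
from tamres.synthetic import NoiseConfig, default_true_parameters, generate_dataset


@pytest.fixture(scope="session")
def truth() -> ModelParameters:
    return default_true_parameters()


@pytest.fixture(scope="session")
def noise_free_dataset(truth):
    return generate_dataset(
        truth, NoiseConfig(growth_cv=0.0, proportion_concentration=np.inf)
    )


@pytest.fixture(scope="session")
def noise_free_observations(noise_free_dataset):
    return assemble_observations(noise_free_dataset)


@pytest.fixture(scope="session")
def jittered_ensemble(truth):
    """A deterministic stand-in ensemble: the truth with small multiplicative
    jitter on every parameter (f_P0 clipped to its domain)."""
    rng = np.random.default_rng(42)
    members = []
    for _ in range(8):
        factors = np.exp(0.05 * rng.standard_normal(19))
        values = truth.to_array() * factors
        values[-1] = min(values[-1], 0.49)
        members.append(ModelParameters.from_array(values))
    return members


@pytest.fixture
def exponential_params():
    """Pure sensitive-population exponential growth at ln 2 per week."""
    return ModelParameters(
        g_S=np.log(2.0), g_P=0.0, g_R1=0.0, g_R2=0.0, d_S=0.0, d_P=0.0,
        k_SP=0.0, k_PR1=0.0, k_PR2=0.0,
        n_SP=1.0, n_PR1=1.0, n_PR2=1.0,
        K_SP=1.0, K_PR1=1.0, K_PR2=1.0,
        k_PS=0.0, k_R1P=0.0, k_R2P=0.0, f_P0=0.0,
    )
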