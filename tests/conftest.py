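import numpy as np
import pytest

from tigerpop import (
    default_parameters,
    default_prior,
    generate_synthetic_environment,
    simulate,
)


@pytest.fixture(scope="session")
def theta():
    return default_parameters()


@pytest.fixture(scope="session")
def prior():
    return default_prior()


@pytest.fixture(scope="session")
def env3y():
    """Three synthetic years at a temperate site (the common driver fixture)."""
    return generate_synthetic_environment(seed=7, years=3)


@pytest.fixture(scope="session")
def warm_env():
    """Constant warm, diapause-free conditions (no season switching)."""
    return generate_synthetic_environment(
        seed=3, years=2, t_mean=25.0, t_amplitude=0.0, t_noise_sd=0.0,
        rain_prob=0.3, latitude=0.0)


@pytest.fixture(scope="session")
def sim3y(env3y, theta):
    return simulate(env3y, theta)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
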