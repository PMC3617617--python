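import numpy as np
import pytest

from icpd.synth import SynthConfig, generate_dataset


@pytest.fixture(scope="session")
def small_config():
    """Reduced generator profile for fast unit tests."""
    return SynthConfig(n_colonies=3, ages=tuple(range(10, 470, 60)), seed=7)


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return generate_dataset(small_config)


@pytest.fixture(scope="session")
def clean_config():
    """Noiseless, outlier-free profile: every screen must pass everything."""
    return SynthConfig(
        n_colonies=3, ages=tuple(range(10, 470, 60)),
        noise_sd={"THAA": 0.0, "FAA": 0.0}, conc_noise_rel=0.0,
        conc_noise_aa=0.0, colony_rate_sd=0.0, outlier_fraction=0.0,
        seed=11)


@pytest.fixture(scope="session")
def clean_dataset(clean_config):
    return generate_dataset(clean_config)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
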