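import numpy as np
import pytest

from swingseg import GeneratorConfig, simulate_dataset


@pytest.fixture(scope="session")
def noiseless_config():
    return GeneratorConfig(noise_acc_g=0.0, noise_gyro_dps=0.0)


@pytest.fixture(scope="session")
def noiseless_swings(noiseless_config):
    """12 noiseless swings, 3 subjects (construction-oracle fixture)."""
    return simulate_dataset(3, 4, noiseless_config, seed=5)


@pytest.fixture(scope="session")
def noisy_swings():
    """24 swings at the default noise level, 4 subjects."""
    return simulate_dataset(4, 6, GeneratorConfig(), seed=3)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
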