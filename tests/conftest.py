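import numpy as np
import pytest

from lickometry import LickGenParams, SensorParams, generate_lick_train


@pytest.fixture(scope="session")
def default_train():
    """One 600 s default-parameter lick train, shared across tests."""
    return generate_lick_train(LickGenParams(seed=42))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture()
def quiet_sensor():
    """Noise-free sensor parameters for deterministic detection tests."""
    return SensorParams(baseline_noise_sd=0.0)
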