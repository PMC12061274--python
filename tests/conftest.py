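import numpy as np
import pytest

from socialfp import SimConfig, default_profiles


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def profiles():
    return default_profiles()


@pytest.fixture
def sim_config():
    return SimConfig(seed=7)


@pytest.fixture
def quiet_config():
    """Noise- and motion-free configuration for analytic checks."""
    return SimConfig(seed=7, noise_sd=0.0, motion_sd=0.0)
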