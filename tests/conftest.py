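import numpy as np
import pytest
from hypothesis import settings

from proofkin import SimulationConfig

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture
def default_config() -> SimulationConfig:
    """The generator's default study conditions."""
    return SimulationConfig(seed=0)


@pytest.fixture
def noiseless_config() -> SimulationConfig:
    """Default conditions with all noise sources and day scales switched off."""
    return SimulationConfig(
        seed=0, cell_noise_cv=0.0, meas_noise_sd=0.0, day_scale_range=(1.0, 1.0)
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
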