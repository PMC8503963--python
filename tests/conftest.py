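import numpy as np
import pytest

from hfokit import SimulationConfig, simulate_clean


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_sim_cfg():
    """A short simulated dataset configuration used across tests.

    60 s at 2000 Hz with 3 bursts per frequency keeps per-test runtime low
    while exercising the same generation path as the full-length datasets.
    """
    return SimulationConfig(duration=60.0, events_per_freq=3, seed=11)


@pytest.fixture(scope="session")
def small_clean_dataset(small_sim_cfg):
    return simulate_clean(small_sim_cfg)
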