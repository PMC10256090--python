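import numpy as np
import pytest

from beeradar import benchmarks, sim


@pytest.fixture(scope="session")
def radar() -> sim.RadarConfig:
    return sim.RadarConfig()


@pytest.fixture(scope="session")
def small_dataset():
    """30 windows/class at default noise and clutter; shared across tests."""
    return benchmarks.make_dataset(30, seed=7)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
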