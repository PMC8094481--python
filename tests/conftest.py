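import numpy as np
import pytest

import speclai as s
from speclai.sensors import trim_reliable


@pytest.fixture(scope="session")
def design44():
    return s.simulate_design(44, seed=7)


@pytest.fixture(scope="session")
def samples44(design44):
    return s.simulate_lai(design44, seed=7)


@pytest.fixture(scope="session")
def dataset(design44, samples44):
    """Default synthetic campaign resampled onto the 125-band grid (seed 7)."""
    return s.simulate_dataset(design44, samples44, s.UHD185_GRID, seed=7)


@pytest.fixture(scope="session")
def trimmed(dataset):
    return trim_reliable(dataset)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
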