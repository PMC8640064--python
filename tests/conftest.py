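import numpy as np
import pytest

from mutpolar.simdata import SimConfig, simulate_dataset


@pytest.fixture(scope="session")
def default_sim():
    """One default-parameter synthetic dataset shared across read-only tests."""
    return simulate_dataset(SimConfig(seed=42))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
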