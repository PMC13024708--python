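import numpy as np
import pytest

from barriereis import CircuitParams, FrequencyGrid, simulate_spectrum


@pytest.fixture(scope="session")
def default_grid():
    return FrequencyGrid.default()


@pytest.fixture(scope="session")
def example_params():
    """A mid-range device parameter set used across modules."""
    return CircuitParams(r1=60.0, rb=25.0, cp=5e-6, q=2e-3, alpha=0.85)


@pytest.fixture(scope="session")
def example_spectrum(example_params, default_grid):
    return simulate_spectrum(example_params, default_grid)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
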