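import numpy as np
import pytest
from hypothesis import settings

from mrsynth.assembly import build_example, example_rng, simulate_basis_set
from mrsynth.spinsim import AcquisitionGrid

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def grid3t():
    """Default 3.0 T / 35 ms acquisition cell."""
    return AcquisitionGrid(b0=3.0, te=0.035)


@pytest.fixture(scope="session")
def basis_cache(grid3t):
    """Full simulated basis set at 3.0 T / 35 ms (shared; ~10 s)."""
    return simulate_basis_set(grid3t)


@pytest.fixture(scope="session")
def records16(grid3t, basis_cache):
    """Sixteen deterministic synthetic examples on the default cell."""
    return [build_example(grid3t, basis_cache, example_rng(1000, 0, i)) for i in range(16)]


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
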