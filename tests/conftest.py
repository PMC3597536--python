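import numpy as np
import pytest

from ebsim import build_aggregate


@pytest.fixture(scope="session")
def packing_100():
    """Relaxed random packing of 100 cells (shared, read-only structure)."""
    return build_aggregate(100, seed=21)


@pytest.fixture(scope="session")
def packing_250():
    return build_aggregate(250, seed=1)


@pytest.fixture(scope="session")
def packing_1000():
    return build_aggregate(1000, seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
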