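import numpy as np
import pytest

from nkmix import generate_landscape


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_landscape():
    """An enumerable N=6, K=2 landscape shared across read-only tests."""
    return generate_landscape(6, 2, seed=42)


@pytest.fixture(scope="session")
def medium_landscape():
    """N=8, K=3 landscape for engine-level oracle checks."""
    return generate_landscape(8, 3, seed=7)
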