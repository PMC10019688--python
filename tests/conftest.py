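import numpy as np
import pytest

from fundusenhance import generate_fundus


@pytest.fixture(scope="session")
def phantom():
    """One default-size phantom shared by read-only tests."""
    return generate_fundus(seed=3, size=640)


@pytest.fixture(scope="session")
def small_phantom():
    """Minimum-size phantom for cheaper tests."""
    return generate_fundus(seed=11, size=256)


@pytest.fixture
def rng():
    return np.random.default_rng(0)


def random_image(rng, h=32, w=32):
    return rng.uniform(0.0, 1.0, size=(h, w, 3))
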