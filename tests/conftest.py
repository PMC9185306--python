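import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def random_rgb(rng):
    """A 16×16 8-bit RGB image."""
    return rng.integers(0, 256, size=(16, 16, 3)).astype(np.uint8)


@pytest.fixture
def random_gray(rng):
    """A 16×16 float gray image in [0, 255]."""
    return rng.uniform(0, 255, size=(16, 16))
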