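import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def random_image(rng):
    """Unmasked random RGB image (values in [1, 255] so no pixel is masked)."""
    return rng.integers(1, 256, size=(40, 30, 3)).astype(np.uint8)


@pytest.fixture
def banded_image(rng):
    """60x50 image whose left 10 columns are masked (all-zero)."""
    img = rng.integers(1, 256, size=(60, 50, 3)).astype(np.uint8)
    img[:, :10] = 0
    return img
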