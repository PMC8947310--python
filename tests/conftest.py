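import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(20260920)


@pytest.fixture
def checker_image():
    """A small non-degenerate RGB test pattern (asymmetric, non-uniform)."""
    rng = np.random.default_rng(7)
    img = rng.integers(10, 246, size=(12, 16, 3), dtype=np.uint8)
    img[0, 0] = (255, 0, 0)  # break any accidental symmetry
    return img
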