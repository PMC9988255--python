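import numpy as np
import pytest

from fiberdens import Micrograph


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def random_micrograph(rng):
    """A small random 8-bit-valued micrograph with range headroom for offsets."""
    def make(h=64, w=64, lo=30, hi=200, seed=None):
        r = np.random.default_rng(seed) if seed is not None else rng
        px = r.integers(lo, hi, size=(h, w, 3)).astype(float)
        return Micrograph(pixels=px, pixel_size_um=300.0 / 1320.0)
    return make
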