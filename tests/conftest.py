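import numpy as np
import pytest

from polarseg.io import LabelMask, Micrograph


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def checker_image():
    """A 64x64 micrograph with reproducible structure."""
    g = np.random.default_rng(7).random((64, 64))
    return Micrograph(g)


@pytest.fixture
def dot_mask():
    """A 64x64 mask with a single small square of foreground."""
    m = np.zeros((64, 64), dtype=np.uint8)
    m[30:34, 40:44] = 1
    return LabelMask(m)


@pytest.fixture
def tiny_dataset(tmp_path):
    """A small on-disk synthetic dataset (8 positives, 4 negatives, 64x64)."""
    from polarseg.synth import generate_dataset

    return generate_dataset(8, 4, "clear", tmp_path / "data", seed=5, size=(64, 64))
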