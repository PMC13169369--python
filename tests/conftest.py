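import numpy as np
import pytest

from apdkit.repr_align import FeatureMatrix, center_columns


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_centered(rng, n, p):
    """Centered FeatureMatrix with integer sample ids 0..n-1."""
    return center_columns(rng.standard_normal((n, p)), tuple(range(n)))


@pytest.fixture
def centered_pair(rng):
    """A seeded (X, Z) pair on 10 shared samples (3 and 2 features)."""
    return random_centered(rng, 10, 3), random_centered(rng, 10, 2)
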