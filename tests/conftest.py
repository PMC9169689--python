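import numpy as np
import pytest

from spmvselect import ConnectivityMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_connectivity(rng, max_dim=60, density_range=(0.01, 1.0)):
    """A small random matrix, possibly with empty rows / full rows."""
    n = int(rng.integers(1, max_dim))
    m = int(rng.integers(1, max_dim))
    p = rng.uniform(*density_range)
    mask = rng.random((n, m)) < p
    a = np.where(mask, rng.uniform(0.1, 1.0, (n, m)), 0.0)
    return ConnectivityMatrix.from_dense(a)


@pytest.fixture
def small_corpus(rng):
    """A deterministic corpus of small random matrices for oracle checks."""
    return [random_connectivity(rng) for _ in range(60)]
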