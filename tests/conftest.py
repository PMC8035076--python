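import numpy as np
import pytest

from dvchrom.genome import BinTable, ChromSizes
from dvchrom.matrix import ContactMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_chrom_sizes():
    return ChromSizes({"chr2L": 300_000, "chr2R": 200_000})


def toeplitz_matrix(n_bins: int, bin_size: int, values) -> ContactMatrix:
    """Translation-invariant matrix with ``values[d]`` at distance d,
    already 'balanced' with unit biases."""
    cs = ChromSizes({"chrT": n_bins * bin_size})
    bins = BinTable(cs, bin_size)
    dense = np.zeros((n_bins, n_bins))
    for d, v in enumerate(values):
        dense += np.diag(np.full(n_bins - d, float(v)), k=d)
        if d:
            dense += np.diag(np.full(n_bins - d, float(v)), k=-d)
    m = ContactMatrix.from_dense(dense, bins)
    m.biases = np.ones(n_bins)
    return m


def random_matrix(
    n_bins: int, bin_size: int, rng, low: float = 1.0, high: float = 20.0
) -> ContactMatrix:
    """Dense random symmetric positive matrix with unit biases."""
    a = rng.uniform(low, high, size=(n_bins, n_bins))
    a = (a + a.T) / 2
    cs = ChromSizes({"chrR": n_bins * bin_size})
    m = ContactMatrix.from_dense(a, BinTable(cs, bin_size))
    m.biases = np.ones(n_bins)
    return m
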