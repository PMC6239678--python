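import itertools

import numpy as np
import pytest

from dupdiv.msio import HaplotypeMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


def random_matrix(rng, n_max=12, s_max=12, n_min=2):
    """A random valid haplotype matrix (segregating columns not enforced)."""
    n = int(rng.integers(n_min, n_max + 1))
    s = int(rng.integers(0, s_max + 1))
    alleles = rng.integers(0, 2, size=(n, s)).astype(np.uint8)
    positions = np.sort(rng.choice(np.arange(1, 10**6), size=s, replace=False)) / 1e6
    return HaplotypeMatrix(alleles, positions, label="empirical", block_length=1000.0)


def brute_force_pi(alleles) -> float:
    """Mean pairwise Hamming distance over all sequence pairs (oracle)."""
    arr = np.asarray(alleles)
    dists = [
        np.sum(arr[i] != arr[j])
        for i, j in itertools.combinations(range(arr.shape[0]), 2)
    ]
    return float(np.mean(dists)) if dists else 0.0
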