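import numpy as np
import pytest

from mirrorphase.model import PoolView


def make_view(alleles: np.ndarray, mate: np.ndarray | None = None) -> PoolView:
    """Wrap a bare (K, M) allele matrix as a conditioning-pool view."""
    alleles = np.asarray(alleles, dtype=np.int8)
    k = alleles.shape[0]
    if mate is None:
        mate = np.full(k, -1, dtype=np.int64)
    return PoolView(alleles=alleles, mate=np.asarray(mate, dtype=np.int64),
                    global_indices=np.arange(k), fixed=np.zeros(k, dtype=bool))


def paired_mate_map(k: int) -> np.ndarray:
    """Mate map pairing consecutive haplotypes (0,1), (2,3), ..."""
    mate = np.arange(k, dtype=np.int64)
    mate[0::2] += 1
    mate[1::2] -= 1
    return mate


@pytest.fixture
def rng():
    return np.random.default_rng(20260922)


def random_instance(rng, k_max=4, m_max=5, e_choices=(0.0, 0.01, 0.1)):
    """A random small pair-HMM instance for oracle comparisons."""
    k = int(rng.integers(2, k_max + 1))
    m = int(rng.integers(2, m_max + 1))
    alleles = rng.integers(0, 2, (k, m)).astype(np.int8)
    g = rng.integers(-1, 3, m).astype(np.int8)  # includes missing
    theta = rng.random(m - 1) * 0.5
    e = float(rng.choice(e_choices))
    if e == 0.0:
        # avoid degenerate zero-likelihood instances: make g consistent
        j, k2 = rng.integers(0, k, 2)
        g = (alleles[j] + alleles[k2]).astype(np.int8)
    return alleles, g, theta, e
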