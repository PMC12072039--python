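import numpy as np
import pytest
from scipy import sparse as sp

from gtgo.core_data import PPINetwork, ProteinCatalog


def make_network(dense: np.ndarray, ids=None) -> PPINetwork:
    """Wrap a dense symmetric weight matrix as a PPINetwork."""
    dense = np.asarray(dense, dtype=np.float64)
    n = dense.shape[0]
    ids = ids or [f"P{i}" for i in range(n)]
    return PPINetwork(
        catalog=ProteinCatalog.from_ids(ids),
        adjacency=sp.csr_matrix(dense),
    )


def random_network(rng: np.random.Generator, n: int, density: float = 0.3) -> PPINetwork:
    upper = np.triu(rng.random((n, n)) < density, k=1) * rng.uniform(0.1, 1.0, (n, n))
    return make_network(upper + upper.T)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
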