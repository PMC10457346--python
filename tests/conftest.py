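import numpy as np
import pytest
from hypothesis import settings

from amynet.connectome import AdjacencyMatrix
from amynet.synthetic import fixture_graphs

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=25)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def graphs():
    """Named benchmark graphs with known metric values."""
    return fixture_graphs(seed=0)


def random_adjacency(rng: np.random.Generator, n: int, p: float = 0.4) -> AdjacencyMatrix:
    """Random Erdos-Renyi-style binary graph for oracle comparisons."""
    a = (rng.uniform(size=(n, n)) < p).astype(np.int8)
    a = np.triu(a, k=1)
    return AdjacencyMatrix("rand", float("nan"), (a + a.T).astype(np.int8))


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240901)
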