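import numpy as np
import pytest
from hypothesis import settings

from regomax.graph_core import DirectedNetwork, build_google_matrix

settings.register_profile("det", derandomize=True, max_examples=30, deadline=None)
settings.load_profile("det")


def make_random_network(rng: np.random.Generator, n: int, p: float = 0.2) -> DirectedNetwork:
    ids = [f"n{i}" for i in range(n)]
    mask = rng.random((n, n)) < p
    np.fill_diagonal(mask, False)
    links = {(ids[i], ids[j]) for i, j in zip(*np.nonzero(mask))}
    return DirectedNetwork(ids, links)


@pytest.fixture
def two_node_net() -> DirectedNetwork:
    """Node 1 cites node 2; node 2 is dangling."""
    return DirectedNetwork(["1", "2"], {("1", "2")})


@pytest.fixture
def two_node_G(two_node_net):
    return build_google_matrix(two_node_net, alpha=0.85)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
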