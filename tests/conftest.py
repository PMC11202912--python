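import networkx as nx
import pytest

from lpsac import erdos_renyi, toy_graph


@pytest.fixture
def toy() -> nx.Graph:
    return toy_graph()


@pytest.fixture
def random_graphs():
    """Factory for batches of small seeded Erdos-Renyi graphs."""

    def make(count: int, n: int = 10, p: float = 0.35, base_seed: int = 1000):
        return [erdos_renyi(n, p, seed=base_seed + i) for i in range(count)]

    return make
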