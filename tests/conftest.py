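import numpy as np
import pytest

from negsel import Graph, SyntheticConfig, hub_skewed_graph


def graph_from_index_pairs(pairs, n=None):
    """Tiny helper: build a Graph from integer pairs with zero-padded labels."""
    nodes = {u for p in pairs for u in p}
    n = max(nodes | {0}) + 1 if n is None else n
    width = len(str(n - 1))
    labelled = [(f"v{u:0{width}d}", f"v{v:0{width}d}") for u, v in pairs]
    extra = [f"v{i:0{width}d}" for i in range(n)]
    return Graph.from_label_pairs(labelled, extra_labels=extra)


@pytest.fixture
def path_graph():
    return graph_from_index_pairs([(0, 1), (1, 2)])


@pytest.fixture
def star5():
    """K1,5 with center index 0."""
    return graph_from_index_pairs([(0, i) for i in range(1, 6)])


@pytest.fixture
def triangle():
    return graph_from_index_pairs([(0, 1), (0, 2), (1, 2)])


@pytest.fixture
def two_cliques():
    """Two disjoint 4-cliques: nodes 0-3 and 4-7."""
    pairs = []
    for base in (0, 4):
        pairs += [(base + i, base + j) for i in range(4) for j in range(i + 1, 4)]
    return graph_from_index_pairs(pairs)


@pytest.fixture
def random_graph():
    rng = np.random.default_rng(42)
    pairs = [
        (i, j)
        for i in range(20)
        for j in range(i + 1, 20)
        if rng.random() < 0.2
    ]
    return graph_from_index_pairs(pairs, n=20)


@pytest.fixture(scope="session")
def hub_graph():
    """Small hub-skewed heterogeneous graph shared across tests."""
    return hub_skewed_graph(
        SyntheticConfig(n_nodes=1000, n_positive_edges=600, n_hubs=15, seed=3)
    )
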