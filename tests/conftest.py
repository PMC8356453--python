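import numpy as np
import pytest

from graphdti.network import PPINetwork


@pytest.fixture
def chain_network():
    """A-B-C chain, both edges confidence 500."""
    net = PPINetwork()
    net.add_edge("A", "B", 500)
    net.add_edge("B", "C", 500)
    return net


@pytest.fixture
def star_network():
    """Target T with 7 leaves at distinct confidences."""
    net = PPINetwork()
    for i, conf in enumerate([900, 850, 800, 750, 700, 650, 600]):
        net.add_edge("T", f"L{i}", conf)
    return net


def random_small_network(rng, n_nodes=None, p=0.5):
    """Random graph with <= 8 nodes for exhaustive-path oracles."""
    if n_nodes is None:
        n_nodes = int(rng.integers(3, 9))
    net = PPINetwork()
    ids = [f"N{i}" for i in range(n_nodes)]
    net.graph.add_nodes_from(ids)
    for i in range(n_nodes):
        for j in range(i + 1, n_nodes):
            if rng.random() < p:
                net.add_edge(ids[i], ids[j], int(rng.integers(150, 1000)))
    return net


def enumerate_shortest_path(net, source, target):
    """Oracle: minimum weight over all simple paths by exhaustive enumeration."""
    import itertools

    if source == target:
        return 0.0
    g = net.graph
    best = np.inf
    nodes = [v for v in g.nodes if v not in (source, target)]
    for r in range(len(nodes) + 1):
        for middle in itertools.permutations(nodes, r):
            path = (source, *middle, target)
            w = 0.0
            ok = True
            for u, v in zip(path[:-1], path[1:]):
                if not g.has_edge(u, v):
                    ok = False
                    break
                w += g.edges[u, v]["weight"]
            if ok:
                best = min(best, w)
    return best
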