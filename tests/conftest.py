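import networkx as nx
import numpy as np
import pytest

from curvgt import WeightedGraph


@pytest.fixture
def single_edge():
    return WeightedGraph(["x", "y"], [("x", "y", 1.0)])


@pytest.fixture
def k3():
    return WeightedGraph(list("abc"), [("a", "b"), ("b", "c"), ("a", "c")])


@pytest.fixture
def p3():
    # path x - z - y; indices x=0, z=1, y=2
    return WeightedGraph(list("xzy"), [("x", "z"), ("z", "y")])


def random_connected_graph(rng, n_max=12, p=0.4, weighted=False):
    """Seeded connected Erdos-Renyi graph as a WeightedGraph."""
    n = int(rng.integers(3, n_max + 1))
    while True:
        G = nx.gnp_random_graph(n, p, seed=int(rng.integers(2**31)))
        if nx.is_connected(G):
            break
    edges = [
        (u, v, float(rng.uniform(0.5, 2.0)) if weighted else 1.0)
        for u, v in G.edges
    ]
    return WeightedGraph(list(G.nodes), edges)
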