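import networkx as nx
import numpy as np
import pytest

from orcnet.network import CorrelationNetwork, shortest_paths


def network_from_shifted(edges: dict[tuple[str, str], float],
                         distance_floor: float = 1e-6) -> CorrelationNetwork:
    """Build a CorrelationNetwork directly from rho_shifted edge values."""
    g = nx.Graph()
    for (a, b), rs in edges.items():
        g.add_edge(a, b, rho=2 * rs - 1, rho_shifted=rs,
                   weight=1.0 / max(rs, distance_floor))
    nodes = sorted(g.nodes)
    d = shortest_paths(g, nodes)
    return CorrelationNetwork(graph=g, nodes=nodes, d=d,
                              is_core={v: False for v in nodes})


def random_connected_network(rng: np.random.Generator, n: int,
                             p: float = 0.5) -> CorrelationNetwork:
    """Random connected graph with rho_shifted sampled in (0.2, 1.0)."""
    while True:
        g = nx.gnp_random_graph(n, p, seed=int(rng.integers(2**31)))
        if nx.is_connected(g) and g.number_of_edges() > 0:
            break
    edges = {
        (f"v{u}", f"v{v}"): float(rng.uniform(0.2, 1.0)) for u, v in g.edges()
    }
    return network_from_shifted(edges)


@pytest.fixture
def barbell_network() -> CorrelationNetwork:
    """Two triangles joined by a single bridge edge, uniform shifted correlations."""
    edges = {}
    for tri in [("a", "b", "c"), ("d", "e", "f")]:
        for i in range(3):
            edges[tuple(sorted((tri[i], tri[(i + 1) % 3])))] = 0.8
    edges[("c", "d")] = 0.8
    return network_from_shifted(edges)


@pytest.fixture
def two_vertex_network() -> CorrelationNetwork:
    return network_from_shifted({("a", "b"): 0.7})
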