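import networkx as nx
import pytest

from nlbc import InputGeneSet, MolecularNetwork


def net_from_edges(edges) -> MolecularNetwork:
    g = nx.Graph()
    g.add_edges_from(edges)
    return MolecularNetwork(g)


@pytest.fixture
def path3():
    """s - v - t."""
    return net_from_edges([("s", "v"), ("v", "t")])


@pytest.fixture
def diamond():
    """Two parallel s-t paths through a and b."""
    return net_from_edges([("s", "a"), ("a", "t"), ("s", "b"), ("b", "t")])


@pytest.fixture
def asymmetric_bridge():
    """Two sources behind private bridges meeting at t."""
    return net_from_edges(
        [("s1", "b1"), ("b1", "t"), ("s2", "b2"), ("b2", "t")]
    )


@pytest.fixture
def bridge_inputs():
    return InputGeneSet({"s1": 2.0, "s2": 1.0, "t": 1.0})


def random_connected_net(rng, max_nodes=30):
    """Small random connected graph for oracle-equivalence checks."""
    n = int(rng.integers(4, max_nodes + 1))
    p = float(rng.uniform(0.1, 0.5))
    g = nx.gnp_random_graph(n, p, seed=int(rng.integers(0, 2**31 - 1)))
    # wire components together so the graph is connected
    comps = [sorted(c) for c in nx.connected_components(g)]
    for a, b in zip(comps, comps[1:]):
        g.add_edge(a[0], b[0])
    g = nx.relabel_nodes(g, {i: f"N{i:02d}" for i in g.nodes})
    return MolecularNetwork(g)


def random_inputs(rng, net, max_size=8):
    nodes = sorted(net.nodes)
    k = int(rng.integers(2, min(max_size, len(nodes)) + 1))
    chosen = rng.choice(nodes, size=k, replace=False)
    weights = {str(g): float(rng.uniform(0.2, 5.0)) for g in chosen}
    return InputGeneSet(weights)
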