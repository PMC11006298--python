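import networkx as nx
import pytest

from ppidiffuse.network import Network


def make_network(edges, extra_nodes=()):
    g = nx.Graph()
    for e in edges:
        if len(e) == 3:
            u, v, w = e
        else:
            (u, v), w = e, 1.0
        g.add_edge(u, v, weight=w)
    g.add_nodes_from(extra_nodes)
    return Network(graph=g, meta={"source": "test", "cutoff": 0.0})


@pytest.fixture
def triangle():
    return make_network([("a", "b"), ("b", "c"), ("a", "c")])


@pytest.fixture
def single_edge():
    return make_network([("a", "b")])


@pytest.fixture
def edgeless3():
    return make_network([], extra_nodes=["a", "b", "c"])


@pytest.fixture
def k10():
    g = nx.complete_graph(10)
    g = nx.relabel_nodes(g, {i: f"n{i}" for i in range(10)})
    nx.set_edge_attributes(g, 1.0, "weight")
    return Network(graph=g, meta={"source": "k10", "cutoff": 0.0})


@pytest.fixture
def star6():
    g = nx.star_graph(5)
    g = nx.relabel_nodes(g, {i: f"s{i}" for i in range(6)})
    nx.set_edge_attributes(g, 1.0, "weight")
    return Network(graph=g, meta={"source": "star", "cutoff": 0.0})
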