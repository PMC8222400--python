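import networkx as nx
import pytest

from reposcreen.network import InteractionNetwork
from reposcreen.simulate import SyntheticScenario


def build_network(edges, nodes=()):
    g = nx.Graph()
    g.add_nodes_from(nodes)
    g.add_edges_from(edges)
    return InteractionNetwork(g)


@pytest.fixture
def path5():
    """Path graph a-b-c-d-e."""
    return build_network([("a", "b"), ("b", "c"), ("c", "d"), ("d", "e")])


@pytest.fixture
def triangle():
    return build_network([("a", "b"), ("b", "c"), ("a", "c")])


@pytest.fixture(scope="session")
def default_study():
    """The default synthetic benchmark study, generated once per session."""
    return SyntheticScenario(seed=20).generate()
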