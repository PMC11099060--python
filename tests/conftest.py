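import networkx as nx
import pytest
from hypothesis import HealthCheck, settings

from onsetnet.multiplex import AggregatedNetwork, Layer, build_multiplex
from onsetnet.synthetic import SyntheticConfig, generate

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


def agg_from_graph(g: nx.Graph) -> AggregatedNetwork:
    """Wrap a plain graph as a single-layer aggregated network."""
    h = nx.Graph()
    h.add_nodes_from(g.nodes)
    for a, b in g.edges:
        h.add_edge(a, b, layers=("ppi",))
    return AggregatedNetwork(graph=h)


@pytest.fixture(scope="session")
def default_bundle():
    """One synthetic bundle at generator defaults."""
    return generate(SyntheticConfig(rng_seed=11))


@pytest.fixture
def toy_multiplex():
    """Two layers over {A..E}: a path in one layer, a chord in the other."""
    l1 = Layer("ppi", frozenset({("A", "B"), ("B", "C"), ("C", "D")}))
    l2 = Layer("pathways", frozenset({("A", "C"), ("D", "E")}))
    return build_multiplex([l1, l2])
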