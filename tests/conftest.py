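import networkx as nx
import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=40,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def study_bundle():
    from netpharm.synthetic_data import study_shaped_bundle

    return study_shaped_bundle()


@pytest.fixture(scope="session")
def table1():
    from netpharm.synthetic_data import builtin_fixture

    return builtin_fixture("ofte_table1")


def random_connected_graph(n: int, p: float, seed: int) -> nx.Graph:
    """A connected G(n, p) graph (largest component relabelled 0..m-1)."""
    graph = nx.gnp_random_graph(n, p, seed=seed)
    component = max(nx.connected_components(graph), key=len)
    return nx.convert_node_labels_to_integers(graph.subgraph(component))


@pytest.fixture
def rng():
    return np.random.default_rng(20171228)
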