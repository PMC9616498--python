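import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import metamap as mm

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def triangle():
    """Unweighted triangle: the smallest regular graph."""
    return mm.Graph.from_edges([("a", "b"), ("b", "c"), ("a", "c")])


@pytest.fixture
def weighted_path():
    """Path a-b-c with weights 1 and 3; stationary rates (1/8, 4/8, 3/8)."""
    return mm.Graph.from_edges([("a", "b", 1.0), ("b", "c", 3.0)])


@pytest.fixture(scope="session")
def clique():
    """Default clique benchmark with its class metadata (seed 1)."""
    return mm.clique_benchmark(seed=1)


@pytest.fixture(scope="session")
def random12():
    """12-node connected Erdos-Renyi fixture with binary metadata."""
    rng = np.random.default_rng(1234)
    nodes = [f"n{k}" for k in range(12)]
    while True:
        edges = [
            (nodes[a], nodes[b], float(rng.uniform(0.5, 2.0)))
            for a in range(12)
            for b in range(a + 1, 12)
            if rng.random() < 0.35
        ]
        try:
            graph = mm.Graph.from_edges(edges, nodes=nodes)
            break
        except mm.GraphError:
            continue
    meta = mm.MetadataMap({v: int(rng.integers(2)) for v in nodes}, "categorical")
    return graph, meta
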