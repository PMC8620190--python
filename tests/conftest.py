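import numpy as np
import pytest

from ended.core_model import AssociationNetwork, Edge, Node, NodeKind


def build_network(node_kinds: dict, edges: list, n_samples: int | None = None):
    """Construct a network from {id: 'taxon'|'env'} and edge tuples.

    Edge tuples are (u, v, score) or (u, v, score, start, duration);
    p and q default to 0.001.
    """
    net = AssociationNetwork(n_samples=n_samples)
    for node_id, kind in node_kinds.items():
        net.add_node(Node(node_id, NodeKind(kind)))
    for spec in edges:
        if len(spec) == 3:
            u, v, score = spec
            start, duration = 0, n_samples or 100
        else:
            u, v, score, start, duration = spec
        net.add_edge(
            Edge(u=u, v=v, score=score, p_value=0.001, q_value=0.001,
                 start=start, duration=duration)
        )
    return net


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_community():
    """A 12-taxon simulated community, module-scoped deterministic input."""
    from ended.simulator import SimulationConfig, simulate_community

    cfg = SimulationConfig(n_taxa=12)
    return simulate_community(cfg, np.random.default_rng(7))
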