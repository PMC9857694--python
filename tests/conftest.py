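import numpy as np
import pytest

from emaplex import MultiplexNetwork, SynthSpec, generate_multiplex


@pytest.fixture
def two_layer_net() -> MultiplexNetwork:
    """Hand-built 5-node, 2-layer multiplex used across unit tests.

    L1: path a-b-c plus edge c-d;  L2: triangle a-b-e.  Node d isolated in
    L2, node e isolated in L1.
    """
    return MultiplexNetwork.from_edges(
        {
            "L1": [("a", "b"), ("b", "c"), ("c", "d")],
            "L2": [("a", "b"), ("b", "e"), ("a", "e")],
        },
        node_ids=["a", "b", "c", "d", "e"],
    )


@pytest.fixture(scope="session")
def synthetic_fixture():
    """The scaled-down study fixture: 2 layers, 200 nodes, Poisson(3)
    degrees, overlap 0.7."""
    net, prov = generate_multiplex(SynthSpec(200, 2, ("poisson", 3.0), 0.7, rng_seed=7))
    return net, prov


def random_multiplex(n: int, m: int, p_edge: float, seed: int) -> MultiplexNetwork:
    """Erdos-Renyi-per-layer multiplex for property tests."""
    rng = np.random.default_rng(seed)
    mats = []
    for _ in range(m):
        a = np.zeros((n, n), dtype=np.int8)
        iu = np.triu_indices(n, k=1)
        a[iu] = rng.random(len(iu[0])) < p_edge
        a = a + a.T
        mats.append(a)
    return MultiplexNetwork([f"v{i}" for i in range(n)], [f"L{k}" for k in range(m)], mats)
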