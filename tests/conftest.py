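import numpy as np
import pytest

from neurodecay import (DecayParameters, DirectedWeightedNetwork,
                        SmallWorldSpec, WeightInitSpec, generate_small_world)


def make_network(n, edges, strengths=None):
    """Small hand-built network from an (src, dst) edge list."""
    edges = np.asarray(edges, dtype=np.int64)
    if strengths is None:
        strengths = np.ones(len(edges))
    return DirectedWeightedNetwork(n=n, src=edges[:, 0], dst=edges[:, 1],
                                   eps0=np.asarray(strengths, dtype=float))


def random_network(rng, n, m, unit_weights=True):
    """Uniformly random simple directed graph with m edges."""
    pairs = set()
    while len(pairs) < m:
        i, j = rng.integers(n, size=2)
        if i != j:
            pairs.add((int(i), int(j)))
    edges = sorted(pairs)
    w = np.ones(m) if unit_weights else rng.uniform(0.05, 1.0, size=m)
    return make_network(n, edges, w)


@pytest.fixture
def three_cycle():
    """Directed 3-cycle A->B->C->A with unit strengths."""
    return make_network(3, [(0, 1), (1, 2), (2, 0)])


@pytest.fixture(scope="session")
def small_world_net():
    """Mid-sized small-world network shared by read-only tests."""
    return generate_small_world(SmallWorldSpec(n=2000, k_out=10, seed=123))


@pytest.fixture
def mouse_params():
    return DecayParameters(p0=0.01, p1=1e-4, tau=30.0, horizon=400.0, seed=0)
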