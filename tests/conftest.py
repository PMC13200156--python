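"""Shared fixtures: small programmatically generated graphs and cohorts."""

import numpy as np
import pytest

from ndmap import Connectome, SyntheticSpec, build_laplacian, generate_connectome


def random_connected_weights(n: int, rng: np.random.Generator, density: float = 0.3):
    """Random symmetric nonnegative weighted adjacency, guaranteed connected
    via a random spanning path."""
    w = np.zeros((n, n))
    iu = np.triu_indices(n, k=1)
    mask = rng.random(iu[0].size) < density
    w[iu] = mask * rng.uniform(0.5, 2.0, size=iu[0].size)
    w = w + w.T
    order = rng.permutation(n)
    for a, b in zip(order[:-1], order[1:]):
        if w[a, b] == 0:
            w[a, b] = w[b, a] = rng.uniform(0.5, 2.0)
    return w


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)


@pytest.fixture
def two_node():
    """Two regions, one unit edge: normalized Laplacian [[1,-1],[-1,1]]."""
    return build_laplacian(np.array([[0.0, 1.0], [1.0, 0.0]]))


@pytest.fixture
def small_connectome(rng):
    """Connected 10-region weighted connectome."""
    w = random_connected_weights(10, rng)
    return Connectome(weights=w, region_ids=[f"R{i:02d}" for i in range(10)])


@pytest.fixture
def modular_connectome():
    """Default 46-region modular synthetic connectome (deterministic)."""
    return generate_connectome(SyntheticSpec(rng_seed=7))
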