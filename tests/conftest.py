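from __future__ import annotations

import random

import pytest

from ewca.network import PPINetwork
from ewca.synthetic import example_network, generate_planted


@pytest.fixture(scope="session")
def fig_network() -> PPINetwork:
    """The 11-protein hand-worked example network."""
    return example_network()


@pytest.fixture(scope="session")
def planted_default():
    """The default planted benchmark (5 complexes, cores 4-8, seed 42)."""
    return generate_planted(seed=42)


def random_er_network(rng: random.Random, n_max: int = 12) -> PPINetwork:
    """Small seeded Erdős–Rényi graph over string-labelled vertices."""
    n = rng.randint(3, n_max)
    p = rng.uniform(0.15, 0.7)
    vertices = [f"v{i}" for i in range(n)]
    edges = [
        (vertices[i], vertices[j])
        for i in range(n)
        for j in range(i + 1, n)
        if rng.random() < p
    ]
    return PPINetwork(vertices=vertices, edges=edges)
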