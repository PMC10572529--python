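from __future__ import annotations

import random

import networkx as nx
import pytest
from hypothesis import settings

from gibbslink import PPINetwork, make_rb1_toy_network

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture
def rb1_network() -> PPINetwork:
    return make_rb1_toy_network()


def random_instance(rng: random.Random, max_nodes: int = 20):
    """A random (network, profile-dict) pair for oracle comparisons.

    Some nodes are left without expression to exercise the covered/uncovered
    distinction; values include exact zeros and ones.
    """
    n = rng.randint(2, max_nodes)
    p = rng.uniform(0.1, 0.7)
    g = nx.gnp_random_graph(n, p, seed=rng.randint(0, 2**31 - 1))
    g = nx.relabel_nodes(g, {i: f"N{i:02d}" for i in g.nodes})
    net = PPINetwork(graph=g, provenance=["random"])
    c = {}
    for node in g.nodes:
        r = rng.random()
        if r < 0.15:
            continue  # uncovered node
        if r < 0.30:
            c[node] = 0.0
        elif r < 0.40:
            c[node] = 1.0
        else:
            c[node] = rng.random()
    return net, c
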