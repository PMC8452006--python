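import numpy as np
import pytest

from plexmod.ga import GAConfig
from plexmod.network import Layer, MultiplexNetwork
from plexmod.scoring import NodeScoreTable


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def path_triangle_net():
    """Two layers over {a, b, c}: a path a-b-c and a triangle."""
    l1 = Layer.from_edges([("a", "b"), ("b", "c")], name="path")
    l2 = Layer.from_edges([("a", "b"), ("b", "c"), ("a", "c")], name="triangle")
    return MultiplexNetwork([l1, l2])


def grid_multiplex(side=8, n_layers=2, seed=0, extra_p=0.08):
    """Toy multiplex: a connected grid backbone in every layer plus random
    per-layer chords, so layers differ but the union stays connected."""
    rng = np.random.default_rng(seed)
    nodes = [f"n{i:02d}" for i in range(side * side)]
    backbone = []
    for r in range(side):
        for c in range(side):
            i = r * side + c
            if c + 1 < side:
                backbone.append((nodes[i], nodes[i + 1]))
            if r + 1 < side:
                backbone.append((nodes[i], nodes[i + side]))
    layers = []
    for k in range(n_layers):
        edges = list(backbone)
        for i in range(len(nodes)):
            for j in range(i + 2, len(nodes)):
                if rng.random() < extra_p:
                    edges.append((nodes[i], nodes[j]))
        layers.append(Layer.from_edges(edges, name=f"layer_{k}"))
    return MultiplexNetwork(layers)


@pytest.fixture
def toy_net():
    return grid_multiplex()


@pytest.fixture
def toy_scores(toy_net):
    """Deterministic scores: ~1/4 of the nodes significant, graded scores."""
    nodes = sorted(toy_net.node_universe)
    raw = {n: (i % 17) / 16 for i, n in enumerate(nodes)}
    significant = {n for i, n in enumerate(nodes) if i % 4 == 0}
    return NodeScoreTable(raw, raw, significant)


@pytest.fixture
def small_cfg():
    return GAConfig(pop_size=16, min_size=4, max_size=10, generations=5, seed=7)
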