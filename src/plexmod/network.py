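"""Multiplex network data model.

A multiplex network is an ordered collection of undirected layers (e.g. a
protein-protein interaction layer, a pathway layer, a co-expression layer)
that share a single node-ID namespace: the same identifier in two layers
refers to the same gene/protein, which is what couples the layers. Edges are
unweighted and undirected; self-loops and duplicate edges are dropped on
load.

Node IDs are opaque, case-sensitive strings. No identifier mapping is
attempted.
"""

from __future__ import annotations

import logging
import re
from collections.abc import Iterable, Set
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx

logger = logging.getLogger(__name__)

# header tokens commonly found on the first line of an edge list
_HEADER_TOKENS = {
    "source", "target", "from", "to", "node1", "node2", "gene1", "gene2",
    "protein1", "protein2", "id1", "id2",
}

_SPLIT = re.compile(r"[,\t ;]+")


@dataclass
class Layer:
    """One undirected, simple interaction layer.

    ``adjacency`` maps every node to the set of its neighbours; isolated
    nodes map to an empty set. ``n_edges`` counts each undirected edge once.
    """

    name: str
    adjacency: dict[str, set[str]] = field(default_factory=dict)
    n_edges: int = 0

    @property
    def nodes(self) -> set[str]:
        return set(self.adjacency)

    def __contains__(self, node: str) -> bool:
        return node in self.adjacency

    def neighbors(self, node: str) -> set[str]:
        return self.adjacency.get(node, set())

    def has_edge(self, u: str, v: str) -> bool:
        return v in self.adjacency.get(u, ())

    def edges(self) -> Iterable[tuple[str, str]]:
        """Yield each undirected edge once, as a sorted pair."""
        for u, nbrs in self.adjacency.items():
            for v in nbrs:
                if u < v:
                    yield (u, v)

    @classmethod
    def from_edges(
        cls,
        edges: Iterable[tuple[str, str]],
        name: str = "layer",
        extra_nodes: Iterable[str] = (),
    ) -> "Layer":
        """Build a layer from an iterable of node pairs.

        Self-loops are discarded and duplicate edges collapse; nodes listed
        in ``extra_nodes`` are kept even when they touch no edge.
        """
        adj: dict[str, set[str]] = {}
        n_edges = 0
        n_loops = 0
        for u, v in edges:
            u, v = str(u), str(v)
            if u == v:
                n_loops += 1
                adj.setdefault(u, set())
                continue
            s = adj.setdefault(u, set())
            if v not in s:
                s.add(v)
                adj.setdefault(v, set()).add(u)
                n_edges += 1
        for node in extra_nodes:
            adj.setdefault(str(node), set())
        if n_loops:
            logger.info("layer %s: dropped %d self-loop(s)", name, n_loops)
        return cls(name=name, adjacency=adj, n_edges=n_edges)

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.adjacency)
        g.add_edges_from(self.edges())
        return g


class MultiplexNetwork:
    """Ordered list of :class:`Layer` objects sharing one node namespace.

    The union graph (all edges of all layers over the union of node sets)
    backs connectivity queries and multiplex neighbourhoods; it is built
    once at construction.
    """

    def __init__(self, layers: list[Layer]):
        if not layers:
            raise ValueError("a multiplex network needs at least one layer")
        self.layers: list[Layer] = list(layers)
        union: dict[str, set[str]] = {}
        for layer in self.layers:
            for node, nbrs in layer.adjacency.items():
                union.setdefault(node, set()).update(nbrs)
        self._union_adj = union
        self.node_universe: set[str] = set(union)
        self._layer_density = [layer_density(l) for l in self.layers]

    @property
    def n_layers(self) -> int:
        return len(self.layers)

    @property
    def layer_densities(self) -> list[float]:
        return list(self._layer_density)

    def union_neighbors(self, node: str) -> set[str]:
        return self._union_adj.get(node, set())

    def union_graph(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self._union_adj)
        for u, nbrs in self._union_adj.items():
            for v in nbrs:
                if u < v:
                    g.add_edge(u, v)
        return g


def load_layer(path: str | Path, name: str | None = None) -> Layer:
    """Read an undirected edge list (two ID columns; extras ignored).

    Accepts tab-, comma-, semicolon- or whitespace-delimited lines. A first
    line whose two ID columns look like column headers (``source``,
    ``target``, ``gene1`` ...) is skipped.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if name is None:
        name = path.stem
    edges: list[tuple[str, str]] = []
    with open(path) as fh:
        for i, line in enumerate(fh):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = _SPLIT.split(line)
            if len(parts) < 2:
                raise ValueError(
                    f"{path}:{i + 1}: expected at least two columns, got {line!r}"
                )
            u, v = parts[0], parts[1]
            if i == 0 and u.lower() in _HEADER_TOKENS and v.lower() in _HEADER_TOKENS:
                continue
            edges.append((u, v))
    layer = Layer.from_edges(edges, name=name)
    if layer.n_edges == 0 and not layer.adjacency:
        raise ValueError(f"{path}: no edges found")
    return layer


def load_node_list(path: str | Path) -> set[str]:
    """Read a one-column file of node IDs (for declaring isolated nodes)."""
    path = Path(path)
    with open(path) as fh:
        return {line.strip() for line in fh if line.strip()}


def layer_density(layer: Layer) -> float:
    """Fraction of realised edges among all node pairs: |E| / (n(n-1)/2)."""
    n = len(layer.adjacency)
    if n < 2:
        raise ValueError(f"layer {layer.name!r} has {n} node(s); density needs >= 2")
    return layer.n_edges / (n * (n - 1) / 2)


def subnetwork_density(members: Set[str], layer: Layer) -> float:
    """Density of the subgraph induced by ``members`` on one layer.

    The denominator uses the full module size even when some members are
    absent from the layer: a module unsupported by a layer is penalised
    rather than excused.
    """
    n = len(members)
    if n < 2:
        raise ValueError("subnetwork density needs at least 2 members")
    internal = count_internal_edges(members, layer)
    return internal / (n * (n - 1) / 2)


def count_internal_edges(members: Set[str], layer: Layer) -> int:
    """Number of layer edges with both endpoints in ``members``."""
    adj = layer.adjacency
    if not isinstance(members, (set, frozenset)):
        members = set(members)
    total = 0
    for u in members:
        nbrs = adj.get(u)
        if nbrs:
            total += len(nbrs & members)
    return total // 2


def normalized_density(members: Set[str], net: MultiplexNetwork) -> float:
    """Sum over layers of subnetwork density over layer density.

    Each layer contributes d_s / d_l, so the result is not bounded by 1:
    a module denser than a layer's background contributes more than 1 from
    that layer.
    """
    total = 0.0
    for layer, d_l in zip(net.layers, net._layer_density):
        if d_l == 0:
            raise ValueError(f"layer {layer.name!r} has zero density")
        total += subnetwork_density(members, layer) / d_l
    return total


def multiplex_neighbors(members: Set[str], net: MultiplexNetwork) -> set[str]:
    """Nodes adjacent to any member in any layer, excluding the members."""
    unknown = set(members) - net.node_universe
    if unknown:
        raise KeyError(f"unknown node IDs: {sorted(unknown)[:5]}")
    out: set[str] = set()
    for u in members:
        out |= net.union_neighbors(u)
    return out - set(members)


def is_connected_in_union(members: Set[str], net: MultiplexNetwork) -> bool:
    """True iff ``members`` induce one connected component on the layer union."""
    if not members:
        raise ValueError("empty member set")
    members = set(members)
    start = next(iter(members))
    seen = {start}
    stack = [start]
    while stack:
        u = stack.pop()
        for v in net.union_neighbors(u) & members:
            if v not in seen:
                seen.add(v)
                stack.append(v)
    return len(seen) == len(members)


def aggregate_layers(net: MultiplexNetwork, name: str = "aggregated") -> MultiplexNetwork:
    """Collapse all layers into a single-layer network (edge-set union).

    Lets the same search run on the flattened network, for comparing
    multiplex against aggregated analyses.
    """
    adj = {u: set(nbrs) for u, nbrs in net._union_adj.items()}
    n_edges = sum(len(nbrs) for nbrs in adj.values()) // 2
    return MultiplexNetwork([Layer(name=name, adjacency=adj, n_edges=n_edges)])


def module_to_graphml(
    members: Set[str], net: MultiplexNetwork, path: str | Path
) -> None:
    """Write the induced multiplex subgraph as GraphML.

    Each edge carries a ``layers`` attribute naming the layer(s) that
    support it.
    """
    g = nx.Graph()
    g.add_nodes_from(sorted(members))
    for layer in net.layers:
        for u in members:
            for v in layer.neighbors(u) & set(members):
                if u < v:
                    if g.has_edge(u, v):
                        g[u][v]["layers"] += "|" + layer.name
                    else:
                        g.add_edge(u, v, layers=layer.name)
    nx.write_graphml(g, str(path))
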