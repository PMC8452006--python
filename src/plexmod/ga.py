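"""Graph-constrained NSGA-II for active-module search.

Individuals are connected subnetworks of the multiplex (connected on the
union of the layers), scored on two objectives to be maximised jointly:

* average node score — mean of the min-max normalised inverse-normal
  transform of the node p-values, in [0, 1];
* normalised density — sum over layers of the module's within-layer density
  divided by that layer's overall density.

All variation operators (multiplex depth-first initialisation, merge-and-
regrow crossover, neighbourhood mutation, duplicate replacement) are
designed so that every individual remains a single connected component with
a size inside [min_size, max_size] at every point of the evolution.

Determinism: every random draw goes through one ``numpy.random.Generator``
and every draw from a set is made after sorting, so a fixed seed yields
identical runs across processes regardless of hash randomisation.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace
from typing import Optional

import networkx as nx
import numpy as np

from .network import (
    MultiplexNetwork,
    is_connected_in_union,
    multiplex_neighbors,
    normalized_density,
)
from .scoring import NodeScoreTable

logger = logging.getLogger(__name__)

RESEED_CAP = 100  # retries when a DFS from a seed cannot reach min_size


@dataclass
class GAConfig:
    """Search parameters.

    Defaults follow the standard configuration for genome-scale multiplex
    networks: a population of 100 modules of 15-50 nodes evolved for 500
    generations with binary tournaments, 80% crossover and 10% mutation.
    """

    pop_size: int = 100
    min_size: int = 15
    max_size: int = 50
    tournament_size: int = 2
    crossover_rate: float = 0.80
    mutation_rate: float = 0.10
    generations: int = 500
    jaccard_dup: float = 0.30      # above this overlap, one of a pair is replaced
    jaccard_merge: float = 0.70    # post-processing merge threshold
    sig_threshold: float = 0.05
    parent_attempts: int = 10
    seed: int = 0

    def __post_init__(self):
        if not (2 <= self.min_size <= self.max_size):
            raise ValueError(
                f"need 2 <= min_size <= max_size, got {self.min_size}, {self.max_size}"
            )
        if self.tournament_size < 2:
            raise ValueError("tournament_size must be >= 2")
        for name in ("crossover_rate", "mutation_rate"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.pop_size < 2:
            raise ValueError("pop_size must be >= 2")

    def with_seed(self, seed: int) -> "GAConfig":
        return replace(self, seed=int(seed))


@dataclass
class Individual:
    """A candidate module: a connected node set plus cached objectives."""

    members: frozenset[str]
    avg_score: Optional[float] = None
    norm_density: Optional[float] = None
    rank: Optional[int] = None
    crowding: float = 0.0

    @property
    def evaluated(self) -> bool:
        return self.avg_score is not None

    @property
    def objectives(self) -> tuple[float, float]:
        if not self.evaluated:
            raise ValueError("individual not evaluated")
        return (self.avg_score, self.norm_density)

    def copy(self) -> "Individual":
        return Individual(
            self.members, self.avg_score, self.norm_density, self.rank, self.crowding
        )

    def __len__(self) -> int:
        return len(self.members)


# ---------------------------------------------------------------------------
# initialisation

def multiplex_dfs(
    net: MultiplexNetwork,
    seed_node: str,
    target_size: int,
    rng: np.random.Generator,
) -> set[str]:
    """Random depth-first growth across layers.

    Each time a node is discovered, one layer is drawn uniformly at random
    and only that layer's neighbours of the node are (shuffled and) pushed.
    Traversal stops at ``target_size`` discovered nodes; if the stack
    empties first the (smaller) reachable set is returned and the caller
    decides whether to re-seed.
    """
    if seed_node not in net.node_universe:
        raise KeyError(f"unknown seed node {seed_node!r}")
    n_layers = net.n_layers
    discovered: set[str] = set()
    stack = [seed_node]
    while stack and len(discovered) < target_size:
        v = stack.pop()
        if v in discovered:
            continue
        discovered.add(v)
        if len(discovered) >= target_size:
            break
        layer = net.layers[int(rng.integers(n_layers))]
        nbrs = sorted(layer.neighbors(v))
        rng.shuffle(nbrs)
        stack.extend(nbrs)
    return discovered


def random_individual(
    net: MultiplexNetwork,
    scores: NodeScoreTable,
    cfg: GAConfig,
    rng: np.random.Generator,
) -> Individual:
    """Grow one module from a random significant seed node.

    The target size is uniform on [min_size, max_size]; seeds whose
    multiplex-DFS reach falls short of min_size are redrawn, up to
    ``RESEED_CAP`` attempts.
    """
    pool = sorted(scores.significant_nodes & net.node_universe)
    if not pool:
        raise ValueError("no significant node present in the network")
    for _ in range(RESEED_CAP):
        seed_node = pool[int(rng.integers(len(pool)))]
        target = int(rng.integers(cfg.min_size, cfg.max_size + 1))
        members = multiplex_dfs(net, seed_node, target, rng)
        if len(members) >= cfg.min_size:
            return Individual(frozenset(members))
    raise RuntimeError(
        f"no significant seed reached min_size={cfg.min_size} "
        f"after {RESEED_CAP} attempts"
    )


def init_population(
    net: MultiplexNetwork,
    scores: NodeScoreTable,
    cfg: GAConfig,
    rng: np.random.Generator,
) -> list[Individual]:
    pop = [random_individual(net, scores, cfg, rng) for _ in range(cfg.pop_size)]
    for ind in pop:
        evaluate(ind, net, scores)
    return pop


# ---------------------------------------------------------------------------
# evaluation and dominance

def evaluate(
    ind: Individual, net: MultiplexNetwork, scores: NodeScoreTable
) -> tuple[float, float]:
    """Compute and cache both objectives on the individual."""
    ind.avg_score = scores.mean_score(ind.members)
    ind.norm_density = normalized_density(ind.members, net)
    return (ind.avg_score, ind.norm_density)


def dominates(a: Individual, b: Individual) -> bool:
    """Pareto dominance for maximisation: >= on both objectives, > on one."""
    a1, a2 = a.objectives
    b1, b2 = b.objectives
    return a1 >= b1 and a2 >= b2 and (a1 > b1 or a2 > b2)


def nondominated_sort(pop: list[Individual]) -> list[list[Individual]]:
    """Fast non-dominated sorting; sets ``rank`` (1-based) on each individual."""
    n = len(pop)
    dominated_by: list[list[int]] = [[] for _ in range(n)]
    n_dominators = [0] * n
    for i in range(n):
        for j in range(i + 1, n):
            if dominates(pop[i], pop[j]):
                dominated_by[i].append(j)
                n_dominators[j] += 1
            elif dominates(pop[j], pop[i]):
                dominated_by[j].append(i)
                n_dominators[i] += 1
    fronts: list[list[Individual]] = []
    current = [i for i in range(n) if n_dominators[i] == 0]
    rank = 1
    while current:
        for i in current:
            pop[i].rank = rank
        fronts.append([pop[i] for i in current])
        nxt = []
        for i in current:
            for j in dominated_by[i]:
                n_dominators[j] -= 1
                if n_dominators[j] == 0:
                    nxt.append(j)
        current = nxt
        rank += 1
    return fronts


def crowding_distance(front: list[Individual]) -> None:
    """Assign the NSGA-II crowding distance within one front.

    Individuals at either extreme of an objective get +inf; interior ones
    accumulate, per objective, the gap between their two neighbours in the
    objective-sorted order, normalised by that objective's range in the
    front (a zero range contributes nothing).
    """
    if not front:
        raise ValueError("empty front")
    for ind in front:
        ind.crowding = 0.0
    n = len(front)
    if n <= 2:
        for ind in front:
            ind.crowding = math.inf
        return
    for key in (lambda x: x.avg_score, lambda x: x.norm_density):
        order = sorted(front, key=key)
        span = key(order[-1]) - key(order[0])
        order[0].crowding = math.inf
        order[-1].crowding = math.inf
        if span == 0:
            continue
        for k in range(1, n - 1):
            if order[k].crowding != math.inf:
                order[k].crowding += (key(order[k + 1]) - key(order[k - 1])) / span
    return


def rank_population(pop: list[Individual]) -> list[list[Individual]]:
    fronts = nondominated_sort(pop)
    for front in fronts:
        crowding_distance(front)
    return fronts


# ---------------------------------------------------------------------------
# selection

def compatible(a: Individual, b: Individual, net: MultiplexNetwork) -> bool:
    """True if the two modules overlap or are adjacent in some layer.

    Compatibility guarantees the union of the two member sets is itself
    connected, which is what makes crossover closed over connectivity.
    """
    if a.members & b.members:
        return True
    for u in a.members:
        if net.union_neighbors(u) & b.members:
            return True
    return False


def _tournament(
    pool: list[Individual], t: int, rng: np.random.Generator
) -> Individual:
    """Size-t tournament: lowest rank wins, ties by largest crowding, then random."""
    k = min(t, len(pool))
    idx = rng.choice(len(pool), size=k, replace=False)
    # random permutation + stable min = uniform choice among full ties
    candidates = [pool[int(i)] for i in idx]
    return min(candidates, key=lambda ind: (ind.rank, -ind.crowding))


def select_parents(
    pop: list[Individual],
    net: MultiplexNetwork,
    cfg: GAConfig,
    rng: np.random.Generator,
) -> Optional[tuple[Individual, Individual]]:
    """Tournament selection of a compatible parent pair.

    The first parent wins a tournament on (rank, crowding). The second
    comes from a tournament over the individuals compatible with the first;
    with a single compatible individual it is taken directly, and with none
    the first parent is discarded and selection restarts. After
    ``parent_attempts`` failed restarts, returns None — the caller then
    injects two fresh random individuals instead of crossing.
    """
    t = cfg.tournament_size
    for _ in range(cfg.parent_attempts):
        p1 = _tournament(pop, t, rng)
        compat = [ind for ind in pop if ind is not p1 and compatible(ind, p1, net)]
        if not compat:
            continue
        if len(compat) == 1:
            return p1, compat[0]
        return p1, _tournament(compat, t, rng)
    return None


# ---------------------------------------------------------------------------
# variation

def _restricted_growth(
    seed_node: str,
    allowed: frozenset[str] | set[str],
    net: MultiplexNetwork,
    target_size: int,
    rng: np.random.Generator,
    breadth_first: bool,
) -> set[str]:
    """Randomised DFS/BFS over the union graph, confined to ``allowed``.

    ``allowed`` must induce a connected union subgraph, so a child of any
    target size up to ``len(allowed)`` is always reachable.
    """
    members: set[str] = set()
    fringe = [seed_node]
    while fringe and len(members) < target_size:
        v = fringe.pop(0 if breadth_first else -1)
        if v in members:
            continue
        members.add(v)
        nbrs = sorted((net.union_neighbors(v) & allowed) - members)
        rng.shuffle(nbrs)
        fringe.extend(nbrs)
    return members


def crossover(
    p1: Individual,
    p2: Individual,
    net: MultiplexNetwork,
    scores: NodeScoreTable,
    cfg: GAConfig,
    rng: np.random.Generator,
) -> tuple[Individual, Individual]:
    """Merge-and-regrow crossover.

    With probability ``crossover_rate`` the parent node sets are merged
    (connected by compatibility) and two children are regrown inside the
    merged set, each from a significant seed node (any merged node if none
    is significant), by randomised DFS or BFS — a fair coin per child —
    truncated at a random size in [min_size, min(max_size, |merged|)].
    Otherwise the children are copies of the parents.
    """
    if rng.random() >= cfg.crossover_rate:
        return p1.copy(), p2.copy()
    merged = frozenset(p1.members | p2.members)
    sig = sorted(merged & scores.significant_nodes)
    pool = sig if sig else sorted(merged)
    hi = min(cfg.max_size, len(merged))
    children = []
    for _ in range(2):
        seed_node = pool[int(rng.integers(len(pool)))]
        target = int(rng.integers(cfg.min_size, hi + 1))
        breadth_first = bool(rng.random() < 0.5)
        members = _restricted_growth(seed_node, merged, net, target, rng, breadth_first)
        children.append(Individual(frozenset(members)))
    return children[0], children[1]


def mutate(
    child: Individual,
    net: MultiplexNetwork,
    scores: NodeScoreTable,
    cfg: GAConfig,
    rng: np.random.Generator,
) -> Individual:
    """Neighbourhood mutation.

    With probability ``mutation_rate``: the removable nodes are the members
    that are neither significant nor articulation points of the induced
    union subgraph. They are removed one at a time (connectivity re-checked
    before each removal, and never below min_size), then as many nodes as
    were removed — or one, if none were — are drawn from the multiplex
    neighbourhood, preferring significant neighbours, up to max_size.
    """
    if rng.random() >= cfg.mutation_rate:
        return child
    members = set(child.members)
    if len(members) > 2:
        g = nx.Graph()
        g.add_nodes_from(members)
        for u in members:
            for v in net.union_neighbors(u) & members:
                if u < v:
                    g.add_edge(u, v)
        articulation = set(nx.articulation_points(g))
    else:
        articulation = set()
    removable = sorted(members - scores.significant_nodes - articulation)
    rng.shuffle(removable)
    removed = 0
    for v in removable:
        if len(members) <= cfg.min_size:
            break
        members.discard(v)
        if is_connected_in_union(members, net):
            removed += 1
        else:
            members.add(v)
    n_add = removed if removed > 0 else 1
    for _ in range(n_add):
        if len(members) >= cfg.max_size:
            break
        nbrs = multiplex_neighbors(members, net)
        if not nbrs:
            logger.info("mutation: no neighbour available to add; skipping addition")
            break
        sig = sorted(nbrs & scores.significant_nodes)
        pool = sig if sig else sorted(nbrs)
        members.add(pool[int(rng.integers(len(pool)))])
    return Individual(frozenset(members))


# ---------------------------------------------------------------------------
# diversity maintenance

def jaccard(a: frozenset[str] | set[str], b: frozenset[str] | set[str]) -> float:
    """|A ∩ B| / |A ∪ B|."""
    if not a or not b:
        raise ValueError("Jaccard of an empty set is undefined")
    inter = len(a & b)
    if inter == 0:
        return 0.0
    return inter / (len(a) + len(b) - inter)


def replace_duplicates(
    pop: list[Individual],
    net: MultiplexNetwork,
    scores: NodeScoreTable,
    cfg: GAConfig,
    rng: np.random.Generator,
) -> list[Individual]:
    """Replace near-duplicate individuals with fresh random ones.

    Pairs are scanned once per call in random order; when a pair's Jaccard
    overlap exceeds ``jaccard_dup`` the dominated member (or a random one if
    neither dominates) is replaced by a newly grown, evaluated individual.
    """
    pop = list(pop)
    n = len(pop)
    pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
    rng.shuffle(pairs)
    for i, j in pairs:
        a, b = pop[i], pop[j]
        if jaccard(a.members, b.members) <= cfg.jaccard_dup:
            continue
        if dominates(a, b):
            loser = j
        elif dominates(b, a):
            loser = i
        else:
            loser = i if rng.random() < 0.5 else j
        fresh = random_individual(net, scores, cfg, rng)
        evaluate(fresh, net, scores)
        pop[loser] = fresh
    return pop


# ---------------------------------------------------------------------------
# generational loop

def next_generation(
    parents: list[Individual],
    net: MultiplexNetwork,
    scores: NodeScoreTable,
    cfg: GAConfig,
    rng: np.random.Generator,
) -> list[Individual]:
    """One elitist generation step: N parents -> N survivors.

    Children are produced by repeated parent selection + crossover +
    mutation (a failed compatible-pair search injects two fresh random
    individuals and skips crossover). The 2N parent/child union goes
    through duplicate replacement, is re-ranked, and the best N survive;
    the last partial front is broken by descending crowding distance.
    """
    children: list[Individual] = []
    while len(children) < cfg.pop_size:
        pair = select_parents(parents, net, cfg, rng)
        if pair is None:
            for _ in range(2):
                fresh = random_individual(net, scores, cfg, rng)
                children.append(fresh)
            continue
        c1, c2 = crossover(pair[0], pair[1], net, scores, cfg, rng)
        c1 = mutate(c1, net, scores, cfg, rng)
        c2 = mutate(c2, net, scores, cfg, rng)
        children.extend([c1, c2])
    children = children[: cfg.pop_size]
    for ind in children:
        if not ind.evaluated:
            evaluate(ind, net, scores)
    union = [ind.copy() for ind in parents] + children
    union = replace_duplicates(union, net, scores, cfg, rng)
    fronts = rank_population(union)
    survivors: list[Individual] = []
    for front in fronts:
        if len(survivors) + len(front) <= cfg.pop_size:
            survivors.extend(front)
        else:
            rest = sorted(front, key=lambda ind: -ind.crowding)
            survivors.extend(rest[: cfg.pop_size - len(survivors)])
            break
    return survivors


def dedup_by_members(pop: list[Individual]) -> list[Individual]:
    """Drop individuals with identical member sets, keeping one of each."""
    seen: set[frozenset[str]] = set()
    out = []
    for ind in sorted(pop, key=lambda i: sorted(i.members)):
        if ind.members not in seen:
            seen.add(ind.members)
            out.append(ind)
    return out


def run_single(
    net: MultiplexNetwork,
    scores: NodeScoreTable,
    cfg: GAConfig,
    rng: np.random.Generator | None = None,
) -> tuple[list[Individual], list[dict]]:
    """Run one full search and return (first Pareto front, convergence log).

    The log records, per generation, the best value of each objective in
    the population. The returned front is deduplicated by member set and
    sorted for stable output.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    pop = init_population(net, scores, cfg, rng)
    rank_population(pop)
    log: list[dict] = []
    for g in range(cfg.generations):
        pop = next_generation(pop, net, scores, cfg, rng)
        best_score = max(ind.avg_score for ind in pop)
        best_density = max(ind.norm_density for ind in pop)
        log.append(
            {"generation": g + 1, "best_avg_score": best_score,
             "best_norm_density": best_density}
        )
        logger.info(
            "gen %d: best avg_score=%.4f best norm_density=%.4f",
            g + 1, best_score, best_density,
        )
    front = [ind for ind in pop if ind.rank == 1]
    return dedup_by_members(front), log
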