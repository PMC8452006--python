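"""NSGA-II core: operators, ranking oracles, invariants, determinism."""

import math

import numpy as np
import pytest

from plexmod.ga import (
    GAConfig,
    Individual,
    compatible,
    crossover,
    crowding_distance,
    dominates,
    evaluate,
    init_population,
    jaccard,
    multiplex_dfs,
    mutate,
    next_generation,
    nondominated_sort,
    random_individual,
    rank_population,
    replace_duplicates,
    run_single,
    select_parents,
)
from plexmod.network import Layer, MultiplexNetwork, is_connected_in_union
from plexmod.scoring import NodeScoreTable

from conftest import grid_multiplex


def ind(score, density, tag=""):
    """Individual with given objectives (members are irrelevant to ranking)."""
    return Individual(frozenset({f"x{score}_{density}_{tag}"}),
                      avg_score=score, norm_density=density)


def assert_valid(individual, net, cfg):
    assert cfg.min_size <= len(individual.members) <= cfg.max_size
    assert is_connected_in_union(individual.members, net)


# ---------------------------------------------------------------------------
# initialisation

class TestMultiplexDFS:
    def test_target_one_is_seed(self, toy_net, rng):
        assert multiplex_dfs(toy_net, "n00", 1, rng) == {"n00"}

    def test_star_graph_forced_shape(self, rng):
        star = Layer.from_edges([("hub", f"leaf{i}") for i in range(5)])
        net = MultiplexNetwork([star])
        out = multiplex_dfs(net, "hub", 3, rng)
        assert len(out) == 3 and "hub" in out

    def test_unknown_seed_errors(self, toy_net, rng):
        with pytest.raises(KeyError):
            multiplex_dfs(toy_net, "nope", 5, rng)

    def test_matches_reference_randomized_dfs_single_layer(self, rng):
        """On one layer the traversal is a plain randomised truncated DFS."""
        def reference_dfs(adj, seed, target, r):
            discovered, stack = set(), [seed]
            while stack and len(discovered) < target:
                v = stack.pop()
                if v in discovered:
                    continue
                discovered.add(v)
                if len(discovered) >= target:
                    break
                r.integers(1)  # mirrors the (degenerate) uniform layer draw
                nbrs = sorted(adj[v])
                r.shuffle(nbrs)
                stack.extend(nbrs)
            return discovered

        net = grid_multiplex(side=6, n_layers=1, seed=5)
        adj = {u: net.union_neighbors(u) for u in net.node_universe}
        for trial in range(30):
            seed_val = int(rng.integers(2**31))
            r1 = np.random.default_rng(seed_val)
            r2 = np.random.default_rng(seed_val)
            got = multiplex_dfs(net, "n00", 12, r1)
            assert got == reference_dfs(adj, "n00", 12, r2)

    def test_output_always_connected(self, toy_net, rng):
        for _ in range(200):
            out = multiplex_dfs(toy_net, "n21", int(rng.integers(2, 20)), rng)
            assert is_connected_in_union(out, toy_net)


class TestInitPopulation:
    def test_invariants_and_seed_rule(self, toy_net, toy_scores, small_cfg, rng):
        pop = init_population(toy_net, toy_scores, small_cfg, rng)
        assert len(pop) == small_cfg.pop_size
        for individual in pop:
            assert_valid(individual, toy_net, small_cfg)
            assert individual.members & toy_scores.significant_nodes
            assert individual.evaluated

    def test_deterministic_given_seed(self, toy_net, toy_scores, small_cfg):
        pops = [
            init_population(toy_net, toy_scores, small_cfg, np.random.default_rng(9))
            for _ in range(2)
        ]
        assert [i.members for i in pops[0]] == [i.members for i in pops[1]]

    def test_no_significant_node_errors(self, toy_net, small_cfg, rng):
        empty = NodeScoreTable({"n00": 1.0}, {"n00": 1.0}, set())
        with pytest.raises(ValueError):
            init_population(toy_net, empty, small_cfg, rng)


# ---------------------------------------------------------------------------
# evaluation, dominance, ranking

class TestEvaluateDominates:
    def test_constant_scores_mean_one(self, path_triangle_net):
        ones = NodeScoreTable({}, {"a": 1.0, "b": 1.0, "c": 1.0}, set())
        individual = Individual(frozenset({"a", "b", "c"}))
        avg, dens = evaluate(individual, path_triangle_net, ones)
        assert avg == 1.0

    def test_matches_brute_force_on_random_modules(self, toy_net, toy_scores, rng):
        """Cached objectives equal a direct re-derivation from definitions."""
        nodes = sorted(toy_net.node_universe)
        for _ in range(25):
            members = set(multiplex_dfs(toy_net, nodes[int(rng.integers(len(nodes)))],
                                        10, rng))
            if len(members) < 2:
                continue
            individual = Individual(frozenset(members))
            avg, dens = evaluate(individual, toy_net, toy_scores)
            assert avg == pytest.approx(
                sum(toy_scores.norm_score(m) for m in members) / len(members))
            expected = 0.0
            n = len(members)
            for layer in toy_net.layers:
                internal = sum(
                    1 for u in members for v in members
                    if u < v and layer.has_edge(u, v))
                d_l = layer.n_edges / (len(layer.nodes) * (len(layer.nodes) - 1) / 2)
                expected += (internal / (n * (n - 1) / 2)) / d_l
            assert dens == pytest.approx(expected)

    def test_layer_order_invariance(self, toy_net, toy_scores):
        flipped = MultiplexNetwork(list(reversed(toy_net.layers)))
        members = frozenset({"n00", "n01", "n02", "n10"})
        a = evaluate(Individual(members), toy_net, toy_scores)
        b = evaluate(Individual(members), flipped, toy_scores)
        assert a == pytest.approx(b)

    @pytest.mark.parametrize("a,b,expected", [
        ((0.9, 2.0), (0.5, 1.0), True),   # strictly better on both
        ((0.9, 1.0), (0.5, 2.0), False),  # incomparable
        ((0.5, 1.0), (0.5, 1.0), False),  # equal
        ((0.9, 1.0), (0.5, 1.0), True),   # one strict, one tied
    ])
    def test_dominance_cases(self, a, b, expected):
        assert dominates(ind(*a, "a"), ind(*b, "b")) is expected

    def test_unevaluated_errors(self):
        with pytest.raises(ValueError):
            dominates(Individual(frozenset({"a"})), ind(0.5, 1.0))


def peel_off_fronts(pop):
    """Brute-force oracle: repeatedly strip the non-dominated subset."""
    remaining = list(pop)
    fronts = []
    while remaining:
        front = [a for a in remaining
                 if not any(dominates(b, a) for b in remaining if b is not a)]
        fronts.append({id(a) for a in front})
        remaining = [a for a in remaining if id(a) not in fronts[-1]]
    return fronts


def crowding_oracle(front):
    """Independent crowding distances (numpy argsort, per-objective gaps)."""
    n = len(front)
    if n <= 2:
        return [math.inf] * n
    out = [0.0] * n
    for vals in (np.array([f.avg_score for f in front]),
                 np.array([f.norm_density for f in front])):
        order = np.argsort(vals, kind="stable")
        out[order[0]] = out[order[-1]] = math.inf
        span = vals[order[-1]] - vals[order[0]]
        if span == 0:
            continue
        for pos in range(1, n - 1):
            i = order[pos]
            if out[i] != math.inf:
                out[i] += (vals[order[pos + 1]] - vals[order[pos - 1]]) / span
    return out


class TestRanking:
    def test_single_individual(self):
        a = ind(0.5, 1.0)
        fronts = nondominated_sort([a])
        assert fronts == [[a]] and a.rank == 1

    def test_one_dominator_peels_first(self):
        top = ind(1.0, 9.0, "top")
        rest = [ind(0.1 * i, 0.5 * i, str(i)) for i in range(1, 5)]
        fronts = nondominated_sort([top] + rest)
        assert fronts[0] == [top]

    def test_matches_peel_off_oracle_random(self, rng):
        for _ in range(30):
            n = int(rng.integers(2, 25))
            pop = [ind(round(float(rng.random()), 2),
                       round(float(rng.random() * 3), 2), str(k))
                   for k in range(n)]
            fronts = nondominated_sort(pop)
            expected = peel_off_fronts(pop)
            assert [{id(a) for a in f} for f in fronts] == expected

    def test_crowding_small_fronts_all_infinite(self):
        front = [ind(0.1, 1.0, "a"), ind(0.9, 0.2, "b")]
        crowding_distance(front)
        assert all(f.crowding == math.inf for f in front)

    def test_crowding_collinear_middle_finite(self):
        front = [ind(0.1, 0.1), ind(0.5, 0.5), ind(0.9, 0.9)]
        crowding_distance(front)
        assert front[0].crowding == math.inf and front[2].crowding == math.inf
        assert front[1].crowding == pytest.approx(2.0)

    def test_crowding_matches_oracle_random(self, rng):
        for _ in range(30):
            n = int(rng.integers(1, 12))
            front = [ind(float(rng.random()), float(rng.random() * 2), str(k))
                     for k in range(n)]
            crowding_distance(front)
            expected = crowding_oracle(front)
            for f, e in zip(front, expected):
                assert f.crowding == pytest.approx(e)

    def test_empty_front_errors(self):
        with pytest.raises(ValueError):
            crowding_distance([])


# ---------------------------------------------------------------------------
# selection

def four_triangles_net():
    """Union graph with four disjoint triangles (mutually incompatible regions)."""
    edges = []
    for k in range(4):
        a, b, c = f"t{k}a", f"t{k}b", f"t{k}c"
        edges += [(a, b), (b, c), (a, c)]
    return MultiplexNetwork([Layer.from_edges(edges)])


class TestCompatibleSelect:
    def test_compatibility_clauses(self, path_triangle_net):
        a = Individual(frozenset({"a", "b"}))
        assert compatible(a, a, path_triangle_net)            # intersection
        b = Individual(frozenset({"c"}))
        assert compatible(a, b, path_triangle_net)            # adjacency
        net = four_triangles_net()
        assert not compatible(Individual(frozenset({"t0a", "t0b"})),
                              Individual(frozenset({"t1a", "t1b"})), net)

    def test_pair_from_compatible_population(self, toy_net, toy_scores, small_cfg, rng):
        pop = init_population(toy_net, toy_scores, small_cfg, rng)
        rank_population(pop)
        p1, p2 = select_parents(pop, toy_net, small_cfg, rng)
        assert p1 in pop and p2 in pop and p1 is not p2
        assert compatible(p1, p2, toy_net)

    def test_single_compatible_is_chosen(self):
        net = four_triangles_net()
        pop = [Individual(frozenset({"t0a", "t0b"}), 0.5, 1.0, rank=1, crowding=1.0),
               Individual(frozenset({"t0b", "t0c"}), 0.4, 1.0, rank=1, crowding=1.0)]
        cfg = GAConfig(pop_size=2, min_size=2, max_size=3)
        p1, p2 = select_parents(pop, net, cfg, np.random.default_rng(0))
        assert {id(p1), id(p2)} == {id(i) for i in pop}

    def test_incompatible_population_signals_no_pair(self):
        net = four_triangles_net()
        pop = [Individual(frozenset({f"t{k}a", f"t{k}b"}), 0.5, 1.0, rank=1,
                          crowding=1.0) for k in range(4)]
        cfg = GAConfig(pop_size=4, min_size=2, max_size=3, parent_attempts=5)
        assert select_parents(pop, net, cfg, np.random.default_rng(0)) is None


# ---------------------------------------------------------------------------
# variation

class TestCrossover:
    def test_rate_zero_copies_parents(self, toy_net, toy_scores, small_cfg, rng):
        cfg = GAConfig(**{**small_cfg.__dict__, "crossover_rate": 0.0})
        pop = init_population(toy_net, toy_scores, cfg, rng)
        c1, c2 = crossover(pop[0], pop[1], toy_net, toy_scores, cfg, rng)
        assert c1.members == pop[0].members and c2.members == pop[1].members
        assert c1 is not pop[0]

    def test_self_cross_stays_within_parent(self, toy_net, toy_scores, small_cfg, rng):
        cfg = GAConfig(**{**small_cfg.__dict__, "crossover_rate": 1.0})
        p = init_population(toy_net, toy_scores, cfg, rng)[0]
        c1, c2 = crossover(p, p, toy_net, toy_scores, cfg, rng)
        for c in (c1, c2):
            assert c.members <= p.members
            assert_valid(c, toy_net, cfg)

    def test_children_connected_and_sized(self, toy_net, toy_scores, small_cfg, rng):
        cfg = GAConfig(**{**small_cfg.__dict__, "crossover_rate": 1.0})
        pop = init_population(toy_net, toy_scores, cfg, rng)
        rank_population(pop)
        for _ in range(300):
            pair = select_parents(pop, toy_net, cfg, rng)
            assert pair is not None
            c1, c2 = crossover(pair[0], pair[1], toy_net, toy_scores, cfg, rng)
            for c in (c1, c2):
                assert_valid(c, toy_net, cfg)
                assert c.members <= pair[0].members | pair[1].members


class TestMutate:
    def test_all_significant_adds_one(self, path_triangle_net):
        scores = NodeScoreTable({}, {n: 1.0 for n in "abc"}, {"a", "b"})
        cfg = GAConfig(pop_size=2, min_size=2, max_size=5, mutation_rate=1.0)
        child = Individual(frozenset({"a", "b"}))
        out = mutate(child, path_triangle_net, scores, cfg, np.random.default_rng(0))
        assert len(out.members) == 3  # |v_p| = 0 -> exactly one addition
        assert child.members < out.members

    def test_significant_articulation_node_kept(self):
        net = MultiplexNetwork([Layer.from_edges([("a", "b"), ("b", "c")])])
        scores = NodeScoreTable({}, {n: 0.5 for n in "abc"}, {"b"})
        cfg = GAConfig(pop_size=2, min_size=2, max_size=4, mutation_rate=1.0)
        for seed in range(10):
            out = mutate(Individual(frozenset({"a", "b", "c"})), net, scores, cfg,
                         np.random.default_rng(seed))
            assert "b" in out.members
            assert is_connected_in_union(out.members, net)
            assert 2 <= len(out.members) <= 4

    def test_rate_zero_identity(self, toy_net, toy_scores, small_cfg, rng):
        cfg = GAConfig(**{**small_cfg.__dict__, "mutation_rate": 0.0})
        child = random_individual(toy_net, toy_scores, cfg, rng)
        assert mutate(child, toy_net, toy_scores, cfg, rng) is child

    def test_preserves_invariants_randomized(self, toy_net, toy_scores, small_cfg, rng):
        cfg = GAConfig(**{**small_cfg.__dict__, "mutation_rate": 1.0})
        for _ in range(500):
            child = random_individual(toy_net, toy_scores, cfg, rng)
            out = mutate(child, toy_net, toy_scores, cfg, rng)
            assert_valid(out, toy_net, cfg)


class TestJaccard:
    def test_cases(self):
        assert jaccard({"a"}, {"a"}) == 1.0
        assert jaccard({"a"}, {"b"}) == 0.0
        a = set(range(15))
        b = set(range(5, 20))
        assert jaccard(a, b) == pytest.approx(0.5)  # 10 shared of 20 total
        with pytest.raises(ValueError):
            jaccard(set(), {"a"})


class TestReplaceDuplicates:
    def test_identical_population_collapses_to_one(self, toy_net, toy_scores,
                                                   small_cfg, rng):
        base = random_individual(toy_net, toy_scores, small_cfg, rng)
        evaluate(base, toy_net, toy_scores)
        pop = [base.copy() for _ in range(5)]
        out = replace_duplicates(pop, toy_net, toy_scores, small_cfg, rng)
        assert sum(1 for i in out if i.members == base.members) == 1
        assert all(i.evaluated for i in out)

    def test_low_overlap_population_unchanged(self, toy_net, toy_scores, rng):
        cfg = GAConfig(pop_size=4, min_size=4, max_size=10, jaccard_dup=1.01)
        pop = init_population(toy_net, toy_scores, cfg, rng)
        out = replace_duplicates(pop, toy_net, toy_scores, cfg, rng)
        assert [i.members for i in out] == [i.members for i in pop]

    def test_dominated_member_of_pair_is_replaced(self, toy_net, toy_scores,
                                                  small_cfg, rng):
        a = random_individual(toy_net, toy_scores, small_cfg, rng)
        overlap_seed = sorted(a.members)[0]
        b_members = multiplex_dfs(toy_net, overlap_seed, len(a.members), rng)
        b = Individual(frozenset(b_members))
        if jaccard(a.members, b.members) <= small_cfg.jaccard_dup:
            b = Individual(frozenset(set(a.members)))  # force the overlap
        a.avg_score, a.norm_density = 0.9, 3.0
        b.avg_score, b.norm_density = 0.1, 0.5
        out = replace_duplicates([a, b], toy_net, toy_scores, small_cfg, rng)
        assert out[0] is a
        assert out[1].members != b.members


# ---------------------------------------------------------------------------
# generational loop

class TestNextGeneration:
    def test_output_size_and_invariants(self, toy_net, toy_scores, small_cfg, rng):
        pop = init_population(toy_net, toy_scores, small_cfg, rng)
        rank_population(pop)
        new = next_generation(pop, toy_net, toy_scores, small_cfg, rng)
        assert len(new) == small_cfg.pop_size
        for i in new:
            assert_valid(i, toy_net, small_cfg)
            assert i.evaluated and i.rank is not None

    def test_elitism_best_objectives_never_drop(self, toy_net, toy_scores, rng):
        cfg = GAConfig(pop_size=16, min_size=4, max_size=10, jaccard_dup=1.01, seed=3)
        pop = init_population(toy_net, toy_scores, cfg, rng)
        rank_population(pop)
        best = (max(i.avg_score for i in pop), max(i.norm_density for i in pop))
        for _ in range(5):
            pop = next_generation(pop, toy_net, toy_scores, cfg, rng)
            now = (max(i.avg_score for i in pop), max(i.norm_density for i in pop))
            assert now[0] >= best[0] - 1e-12 and now[1] >= best[1] - 1e-12
            best = now

    def test_stationary_without_variation(self, toy_net, toy_scores, rng):
        cfg = GAConfig(pop_size=12, min_size=4, max_size=10, crossover_rate=0.0,
                       mutation_rate=0.0, jaccard_dup=1.01)
        pop = init_population(toy_net, toy_scores, cfg, rng)
        rank_population(pop)
        before = {i.members for i in pop}
        new = next_generation(pop, toy_net, toy_scores, cfg, rng)
        assert {i.members for i in new} <= before
        # the non-dominated set is fully retained
        first = {i.members for i in pop if i.rank == 1}
        assert first <= {i.members for i in new}


class TestRunSingle:
    def test_gen_zero_returns_initial_front(self, toy_net, toy_scores):
        cfg = GAConfig(pop_size=12, min_size=4, max_size=10, generations=0, seed=5)
        front, log = run_single(toy_net, toy_scores, cfg)
        assert log == []
        rng = np.random.default_rng(cfg.seed)
        pop = init_population(toy_net, toy_scores, cfg, rng)
        rank_population(pop)
        expected = {i.members for i in pop if i.rank == 1}
        assert {i.members for i in front} == expected

    def test_front_invariants(self, toy_net, toy_scores, small_cfg):
        front, log = run_single(toy_net, toy_scores, small_cfg)
        assert len(log) == small_cfg.generations
        members_seen = set()
        for i in front:
            assert_valid(i, toy_net, small_cfg)
            assert i.members not in members_seen
            members_seen.add(i.members)
        for a in front:
            for b in front:
                if a is not b:
                    assert not dominates(a, b)

    def test_identical_seed_identical_front(self, toy_net, toy_scores, small_cfg):
        f1, _ = run_single(toy_net, toy_scores, small_cfg)
        f2, _ = run_single(toy_net, toy_scores, small_cfg)
        assert [i.members for i in f1] == [i.members for i in f2]
        assert [i.objectives for i in f1] == [i.objectives for i in f2]
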