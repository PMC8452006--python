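# Methods

## Model

A multiplex network is a list of undirected simple layers `l = 1..L` over a
shared node namespace; a node is coupled to itself across layers by
identity of its ID, so the coupling is never materialised. A candidate
module is a node set `S` that induces one connected component on the
*union* of the layer edge sets (an edge in any layer counts). Two
objectives are maximised:

1. `NodesScore(S) = (1/|S|) Σ_{i∈S} Score_i^norm`, where
   `Score_i = Φ⁻¹(1 − p_i)` and `Score^norm` is the min–max rescale of
   `Score` over the scored nodes. `p_i` may be a raw p-value or an FDR —
   whichever column the caller selects. p-values are clamped to
   `[1e−16, 1 − 1e−16]` before the quantile so the transform stays finite;
   the subsequent min–max rescale makes the clamp's exact value
   immaterial in practice. Nodes absent from the expression table carry
   score 0 and are never significant, so modules may recruit unmeasured
   genes but gain no score from them. Because the rescale is affine, the
   average is in `[0, 1]` and invariant to affine changes of the raw
   scores.
2. `D_norm(S) = Σ_l d_s(l) / d_l`, where `d = |E_t| / (n(n−1)/2)` for the
   relevant node count `n`. Each layer's `d_l` uses that layer's own node
   count, not the universe size. `d_s(l)` uses the full module size `|S|`
   even when some module nodes are absent from layer `l`: a layer that
   does not support the module dilutes its density there, rather than
   being excused. `D_norm` rewards modules denser than each layer's
   background and can exceed 1.

Significance of a node is `p < threshold` (strict, default 0.05). The
benchmark's DE caller uses `p ≤ α` (inclusive) as its own convention; the
score table accepts an explicit significant set so both conventions
coexist.

## Search

The evolutionary loop is an elitist, two-objective NSGA-II with
graph-aware operators. Invariant: every individual, at every point it is
member of a population, is connected in the layer union with
`MinS ≤ |S| ≤ MaxS`.

- **Initialisation.** Each of `N` individuals grows by a *multiplex DFS*
  from a seed drawn uniformly from the significant nodes, to a target size
  uniform on `[MinS, MaxS]`. The multiplex DFS draws, at each node
  discovery, one layer uniformly at random and pushes that node's
  (shuffled) neighbours in that layer only — traversals thus weave through
  layers. Seeds whose reach falls below `MinS` are redrawn (cap 100).
- **Ranking.** Fast non-dominated sorting into Pareto fronts (rank 1 =
  non-dominated), then crowding distances per front: extreme individuals
  per objective get +∞, interior ones sum neighbour gaps normalised by the
  front's per-objective range (a zero range contributes 0).
- **Parent selection.** Tournament of size `t` on (rank, crowding; full
  ties broken uniformly). The mate must be *compatible* — overlapping or
  adjacent in some layer — which guarantees the merged parent set is
  connected. With `≥ 2` compatibles the mate wins a tournament over them
  (effective size `min(t, #compatibles)`); with exactly one it is taken
  directly; with none, a fresh first parent is drawn. After 10 fruitless
  restarts the pair is abandoned and two fresh random individuals join the
  children instead.
- **Crossover** (rate `c`). The parents' union is the growth substrate;
  two children regrow inside it from significant seed nodes (any merged
  node if none is significant), each by randomised DFS or BFS (fair coin
  per child) truncated at a size uniform on `[MinS, min(MaxS, |merged|)]`.
  The traversal uses the union-graph adjacency restricted to the merged
  set, so any target size is always reachable; per-step layer sampling
  inside a restricted set could dead-end below `MinS`.
- **Mutation** (rate `m`). Removable nodes are members that are neither
  significant nor articulation points of the induced union subgraph. They
  are removed one at a time, re-checking connectivity before each removal
  and never dropping below `MinS` (the articulation set is computed once;
  sequential removals can change it, hence the re-check). Then as many
  nodes as were removed — or one, if none — are added from the multiplex
  neighbourhood, drawn uniformly among significant neighbours when any
  exist, else among all neighbours, capped at `MaxS`.
- **Duplicate replacement.** In the 2N parent∪children pool, each pair is
  checked once per generation in random order; when Jaccard overlap
  exceeds `J_t` (strict), the dominated member — or a random one of an
  incomparable pair — is replaced by a freshly grown, evaluated
  individual. This keeps diversity and deters premature convergence.
- **Elitist selection.** The pool is re-ranked after replacement (pool →
  replace → re-rank → select); whole fronts are taken until one does not
  fit, which is cut by descending crowding distance. The best individuals
  therefore never regress between generations when replacement is off;
  with replacement on, a near-duplicate of the best can be swapped out,
  which is the intended diversity/elitism trade-off.
- **Stopping.** A fixed number of generations; the result is the final
  population's rank-1 front, deduplicated by member set.

Multiple independent runs use seeds derived as `root_seed + run_index`
(mod 2³¹); their fronts are pooled, deduplicated and re-ranked, and the new
rank-1 set is the *accumulated Pareto front*. A reporting-only
post-processing step then repeatedly merges the pair of modules with the
highest Jaccard overlap while it exceeds `J_t2`; unions re-enter the pool,
so chains of mutually similar modules collapse transitively, and merged
modules may exceed `MaxS`. Merge order matters in principle;
highest-overlap-first with recomputation is used and each merge is logged.

## Parameters

| name | meaning | default |
|---|---|---|
| `N` (`pop_size`) | population size | 100 |
| `MinS` / `MaxS` | module size bounds (nodes) | 15 / 50 |
| `t` | tournament size | 2 |
| `c` | crossover rate | 0.80 |
| `m` | mutation rate | 0.10 |
| `gen` | generations per run | 500 |
| `J_t` | duplicate-replacement Jaccard threshold | 0.30 |
| `J_t2` | post-processing merge threshold | 0.70 |
| `sig_threshold` | node-significance p/FDR cut | 0.05 |
| `parent_attempts` | compatible-pair restarts before giving up | 10 |

The size range 15–50 matches the scale of functional communities in
biological networks; sparse layers bias results toward `MinS`, so that
bound should be chosen deliberately. A low `J_t` keeps diversity high; a
high `J_t2` merges only near-identical modules — at low values the
small-world property of biological networks can collapse everything into
one giant module.

## Benchmark

The benchmark plants a connected foreground set FG (default 20 genes) —
grown by seed-and-select (uniform random frontier additions) on the layer
union, or supplied explicitly — and simulates expression: in the 100 case
samples FG genes draw from Normal(5, 1) and background genes from
Normal(2, 1); in the 10 control samples all genes draw from Normal(2, 1);
all draws i.i.d. This is a strong-signal regime (3 SDs). Differential
expression is then called per gene with a two-sided two-sample t-test at
`p ≤ 0.05`, deliberately uncorrected, which floods the significant set
with ≈5% of the background (~490 expected calls on 9425 genes, of which
only 20 are real) and makes precision the hard part of recovery. Recovery
is scored as the F1 of the union of the accumulated-front module node
sets against FG, with background genes in that union counted as false
positives.

The pooled-variance (Student) t-test is the default: the simulation is
homoscedastic by construction, where the pooled test is exact, and with
only 10 controls the Welch approximation is measurably anti-conservative
(empirical type-I ≈5.3%, inflating the significant count by ~5%). Welch
(`equal_var=False`) remains available for real, heteroscedastic data.

### Synthetic networks

`planted_multiplex` generates self-contained fixtures: each layer is an
Erdős–Rényi graph (default 500 nodes, edge probability 0.008, i.e. mean
degree 4 — the sparsity regime of curated interaction layers), and one
common node set (default 15 nodes) additionally receives within-set edges
with probability 0.9 per layer, making it far denser than background in
every layer. Spanning paths over the planted set and over all nodes
guarantee connectivity. What this emulates: a sparse multiplex with one
module that is both dense and (once expression is simulated on it)
high-scoring. What it does not emulate: the heavy-tailed degree
distributions, inter-layer degree correlations, modular/small-world
structure and node-coverage differences of real interaction networks, nor
RNA-seq count noise. Passing the planted-recovery tests therefore shows
the optimizer finds a strong signal in a sparse graph; it does not
certify performance on genome-scale networks, where overlapping dense
regions and uneven annotation make both objectives noisier.

## Numerical and reproducibility choices

- All randomness flows through one `numpy.random.Generator` per run; any
  draw from an unordered set first sorts the node IDs, so runs are
  bit-reproducible across processes and immune to hash randomisation.
- Dominance uses exact float comparisons; equal objective pairs do not
  dominate each other.
- Degenerate inputs fail loudly: densities need ≥ 2 nodes, normalisation
  needs ≥ 2 distinct raw scores, a zero-density layer makes `D_norm`
  undefined, and a score table must intersect the network's nodes.
- Genes constant across all samples get p = 1 (logged) rather than NaN.
- Test and demonstration problem sizes (toy grids of 64 nodes; 500-node
  planted benchmarks with `N=40`, `gen=50`, 5 runs) were chosen so the
  whole suite exercises every operator at volume while staying
  interactive; genome-scale runs use the defaults above and scale roughly
  linearly in `N × gen × runs`.

## Known limitations

- Unweighted, undirected edges only; inter-layer coupling is node
  identity, nothing richer.
- Two objectives, fixed; no adaptive rates, no surrogate evaluation.
- Runtime at published scale (100 individuals × 500 generations × 30 runs
  on ~10⁴-node multiplexes) is hours per run in pure Python; the
  generational loop is the natural target for native-code optimisation.
- The accumulated front is deduplicated by exact member-set identity;
  modules differing by one node are distinct until the post-merge step.
- No statistical significance test of modules against random subnetworks
  is performed; the Pareto front is reported as-is.
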