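"""Multi-run orchestration and post-processing.

A stochastic search is run several times; the rank-1 fronts of all runs are
pooled, re-ranked, and the new first Pareto front — the *accumulated*
front — is the final result. A reporting-only merge step then collapses
modules whose node overlap exceeds a Jaccard threshold, since independent
runs often rediscover near-identical modules.
"""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import dataclass
from pathlib import Path

from .ga import (
    GAConfig,
    Individual,
    dedup_by_members,
    evaluate,
    jaccard,
    nondominated_sort,
    run_single,
)
from .network import MultiplexNetwork, module_to_graphml
from .scoring import NodeScoreTable

logger = logging.getLogger(__name__)


@dataclass
class RunResult:
    run_index: int
    front: list[Individual]
    convergence: list[dict]


def run_many(
    net: MultiplexNetwork,
    scores: NodeScoreTable,
    cfg: GAConfig,
    n_runs: int,
    out_dir: str | Path | None = None,
) -> list[RunResult]:
    """Independent searches with per-run seeds derived as ``cfg.seed + i``.

    Results depend only on the run's own derived seed, so runs are
    order-independent and any subset can be reproduced in isolation. When
    ``out_dir`` is given each run is persisted as soon as it finishes.
    """
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    results = []
    for i in range(n_runs):
        run_cfg = cfg.with_seed((cfg.seed + i) % (2**31))
        front, log = run_single(net, scores, run_cfg)
        result = RunResult(run_index=i, front=front, convergence=log)
        results.append(result)
        logger.info("run %d/%d: %d module(s) on the first front", i + 1, n_runs, len(front))
        if out_dir is not None:
            save_run(result, scores, Path(out_dir))
    return results


def accumulate_pareto_front(results: list[RunResult]) -> list[Individual]:
    """Rank-1 individuals of the pooled, deduplicated fronts of all runs."""
    if not results:
        raise ValueError("no run results")
    pool = dedup_by_members([ind for r in results for ind in r.front])
    fronts = nondominated_sort(pool)
    return dedup_by_members(fronts[0])


def merge_similar_modules(
    front: list[Individual],
    net: MultiplexNetwork,
    scores: NodeScoreTable,
    threshold: float,
) -> list[Individual]:
    """Greedily merge overlapping modules (highest Jaccard first).

    While any pair overlaps above ``threshold``, the most-overlapping pair
    is replaced by its union, which re-enters the pool — so chains of
    mutually similar modules collapse transitively. Merged modules are
    re-evaluated; they may exceed the search's size limit, as merging is a
    reporting step, not a search step.
    """
    if not front:
        raise ValueError("empty front")
    pool = [set(ind.members) for ind in dedup_by_members(front)]
    while len(pool) > 1:
        best = None
        best_j = threshold
        for i in range(len(pool)):
            for j in range(i + 1, len(pool)):
                jac = jaccard(pool[i], pool[j])
                if jac > best_j:
                    best_j = jac
                    best = (i, j)
        if best is None:
            break
        i, j = best
        merged = pool[i] | pool[j]
        logger.info(
            "merging two modules (|A|=%d, |B|=%d, J=%.3f) into one of %d nodes",
            len(pool[i]), len(pool[j]), best_j, len(merged),
        )
        pool = [m for k, m in enumerate(pool) if k not in (i, j)]
        pool.append(merged)
    out = []
    for members in sorted(pool, key=sorted):
        ind = Individual(frozenset(members))
        evaluate(ind, net, scores)
        out.append(ind)
    return out


# ---------------------------------------------------------------------------
# serialization

def save_run(result: RunResult, scores: NodeScoreTable, out_dir: Path) -> None:
    """Write one run's modules (TSV) and convergence log (CSV)."""
    out_dir.mkdir(parents=True, exist_ok=True)
    mod_path = out_dir / f"run_{result.run_index:03d}_modules.tsv"
    with open(mod_path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(["module", "node", "norm_score", "significant"])
        for k, ind in enumerate(result.front):
            for node in sorted(ind.members):
                w.writerow(
                    [k, node, f"{scores.norm_score(node):.6g}",
                     int(scores.is_significant(node))]
                )
    conv_path = out_dir / f"run_{result.run_index:03d}_convergence.csv"
    with open(conv_path, "w", newline="") as fh:
        w = csv.DictWriter(
            fh, fieldnames=["generation", "best_avg_score", "best_norm_density"]
        )
        w.writeheader()
        for row in result.convergence:
            w.writerow(row)


def save_final(
    modules: list[Individual],
    net: MultiplexNetwork,
    scores: NodeScoreTable,
    cfg: GAConfig,
    out_dir: Path,
    graphml: bool = True,
) -> Path:
    """Write the final module set: JSON summary plus one GraphML per module."""
    out_dir.mkdir(parents=True, exist_ok=True)
    summary = {
        "config": {
            "pop_size": cfg.pop_size, "min_size": cfg.min_size,
            "max_size": cfg.max_size, "tournament_size": cfg.tournament_size,
            "crossover_rate": cfg.crossover_rate, "mutation_rate": cfg.mutation_rate,
            "generations": cfg.generations, "jaccard_dup": cfg.jaccard_dup,
            "jaccard_merge": cfg.jaccard_merge, "sig_threshold": cfg.sig_threshold,
            "seed": cfg.seed,
        },
        "modules": [
            {
                "id": k,
                "size": len(ind.members),
                "avg_score": ind.avg_score,
                "norm_density": ind.norm_density,
                "nodes": sorted(ind.members),
            }
            for k, ind in enumerate(modules)
        ],
    }
    path = out_dir / "modules.json"
    with open(path, "w") as fh:
        json.dump(summary, fh, indent=1, sort_keys=True)
        fh.write("\n")
    if graphml:
        for k, ind in enumerate(modules):
            module_to_graphml(ind.members, net, out_dir / f"module_{k:03d}.graphml")
    return path


def load_modules(path: str | Path) -> list[Individual]:
    """Reload modules from a ``modules.json`` summary (objectives not re-checked)."""
    with open(path) as fh:
        summary = json.load(fh)
    return [
        Individual(
            frozenset(m["nodes"]),
            avg_score=m.get("avg_score"),
            norm_density=m.get("norm_density"),
        )
        for m in summary["modules"]
    ]
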