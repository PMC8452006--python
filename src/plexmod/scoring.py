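"""Node scoring from differential-expression statistics.

Each node carries a p-value (or FDR) from some upstream test. The raw score
is the inverse standard-normal transform of 1 - p, so small p-values map to
large positive scores. Raw scores are then min-max rescaled to [0, 1] over
the scored nodes, which makes the module-level average score commensurable
with the density objective. Nodes missing from the table score 0 and are
never significant.
"""

from __future__ import annotations

import logging
from collections.abc import Iterable, Mapping, Set
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
from scipy.stats import norm

logger = logging.getLogger(__name__)

# keeps the normal quantile finite for p in {0, 1} after float round-off
P_CLAMP = 1e-16


@dataclass(frozen=True)
class DERecord:
    """One node's differential-expression result (p or FDR, caller's choice)."""

    node: str
    pvalue: float
    log2fc: float | None = None

    def __post_init__(self):
        if not (0.0 < self.pvalue <= 1.0):
            raise ValueError(f"pvalue must be in (0, 1], got {self.pvalue}")


class NodeScoreTable:
    """Per-node raw score, normalised score and significance flag.

    Only nodes present in the expression table carry a score; any other
    node queried returns 0.0 / not significant, so modules may include
    unmeasured genes without those genes contributing to the score.
    """

    def __init__(
        self,
        raw: Mapping[str, float],
        norm_scores: Mapping[str, float],
        significant: Set[str],
        log2fc: Mapping[str, float] | None = None,
    ):
        self._raw = dict(raw)
        self._norm = dict(norm_scores)
        self.significant_nodes: frozenset[str] = frozenset(significant)
        self.log2fc = dict(log2fc or {})

    def raw_score(self, node: str) -> float:
        return self._raw.get(node, 0.0)

    def norm_score(self, node: str) -> float:
        return self._norm.get(node, 0.0)

    def is_significant(self, node: str) -> bool:
        return node in self.significant_nodes

    def mean_score(self, members: Iterable[str]) -> float:
        members = list(members)
        if not members:
            raise ValueError("empty member set")
        return sum(self._norm.get(m, 0.0) for m in members) / len(members)

    @property
    def scored_nodes(self) -> set[str]:
        return set(self._norm)


def compute_raw_score(pvalue: float) -> float:
    """Inverse standard-normal CDF of 1 - p, with p clamped away from {0, 1}."""
    if not (0.0 < pvalue <= 1.0):
        raise ValueError(f"pvalue must be in (0, 1], got {pvalue}")
    p = min(max(pvalue, P_CLAMP), 1.0 - P_CLAMP)
    return float(norm.ppf(1.0 - p))


def normalize_scores(raw: Mapping[str, float]) -> dict[str, float]:
    """Min-max rescale raw scores to [0, 1]; order-preserving."""
    if len(raw) < 2:
        raise ValueError("need at least 2 scored nodes to normalise")
    lo = min(raw.values())
    hi = max(raw.values())
    if hi == lo:
        raise ValueError("all raw scores are equal; normalisation is undefined")
    span = hi - lo
    return {node: (score - lo) / span for node, score in raw.items()}


def build_score_table(
    records: Iterable[DERecord],
    threshold: float,
    universe: Set[str],
    significant_override: Set[str] | None = None,
) -> NodeScoreTable:
    """Score every node of ``universe`` from its DE record.

    A node is significant when its p-value is strictly below ``threshold``
    and the node exists in the network; ``significant_override`` replaces
    that rule with an explicit set (used when the upstream test applied a
    different significance convention).
    """
    records = list(records)
    if not records:
        raise ValueError("no DE records")
    if not (0.0 < threshold < 1.0):
        raise ValueError(f"threshold must be in (0, 1), got {threshold}")
    raw: dict[str, float] = {}
    pvals: dict[str, float] = {}
    fc: dict[str, float] = {}
    for rec in records:
        if rec.node not in universe:
            continue
        raw[rec.node] = compute_raw_score(rec.pvalue)
        pvals[rec.node] = rec.pvalue
        if rec.log2fc is not None:
            fc[rec.node] = rec.log2fc
    if not raw:
        raise ValueError("no DE record matches any network node")
    norm_scores = normalize_scores(raw)
    if significant_override is not None:
        significant = set(significant_override) & set(universe)
    else:
        significant = {n for n, p in pvals.items() if p < threshold}
    logger.info(
        "scored %d/%d nodes, %d significant", len(raw), len(universe), len(significant)
    )
    return NodeScoreTable(raw, norm_scores, significant, fc)


def load_de_table(
    path: str | Path,
    node_col: str = "gene",
    p_col: str = "pvalue",
    fc_col: str | None = "log2fc",
) -> list[DERecord]:
    """Read a CSV/TSV differential-expression table into records.

    ``p_col`` may point at a raw p-value or an FDR column; whichever the
    caller selects feeds the score.
    """
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    df = pd.read_csv(path, sep=sep)
    for col in (node_col, p_col):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col!r} (have {list(df.columns)})")
    has_fc = fc_col is not None and fc_col in df.columns
    fcs = df[fc_col] if has_fc else [None] * len(df)
    out = []
    for node, p, fc in zip(df[node_col], df[p_col], fcs):
        out.append(
            DERecord(
                node=str(node),
                pvalue=float(p),
                log2fc=float(fc) if fc is not None and pd.notna(fc) else None,
            )
        )
    return out
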