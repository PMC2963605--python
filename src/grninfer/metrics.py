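"""Topology and prediction metrics: AUPR, relative rank, binned error.

AUPR walks the ranked edge list top-down, accumulating the step-wise
(rectangular) area: each true edge adds precision * (1/n_gold) to the
area. A perfect ranking (all true edges first) scores exactly 1; a random
ranking scores about the edge density, which is near zero for sparse
networks. The relative rank of a true edge is its 1-based position in the
full ranking divided by P = N(N-1) — a per-edge error in (0, 1].
"""

from __future__ import annotations

import numpy as np

from .datamodel import (
    ExpressionMatrix,
    GoldStandard,
    KnockoutMap,
    RankedEdgeList,
    natural_gene_key,
)

__all__ = [
    "complete_ranking",
    "aupr",
    "relative_ranks",
    "binned_error_by_regulator_expression",
    "pr_curve",
]


def complete_ranking(ranked: RankedEdgeList, gold: GoldStandard) -> list[tuple[str, str]]:
    """The ranked (regulator, target) pairs extended to the full universe.

    Pairs missing from the list are appended with implicit score 0 in
    deterministic (regulator, target) natural order.
    """
    listed = [(reg, tgt) for reg, tgt, _ in ranked]
    seen = set(listed)
    known = set(gold.gene_ids)
    for reg, tgt in listed:
        if reg not in known or tgt not in known:
            raise ValueError(f"ranked edge {reg}->{tgt} outside the gene universe")
    order = sorted(gold.gene_ids, key=natural_gene_key)
    for reg in order:
        for tgt in order:
            if reg != tgt and (reg, tgt) not in seen:
                listed.append((reg, tgt))
    return listed


def pr_curve(
    ranked: RankedEdgeList, gold: GoldStandard
) -> tuple[np.ndarray, np.ndarray]:
    """Pointwise precision and recall after each edge of the full ranking."""
    if gold.n_edges == 0:
        raise ValueError("gold standard has no edges; AUPR undefined")
    pairs = complete_ranking(ranked, gold)
    hits = np.fromiter(((p in gold.edges) for p in pairs), dtype=bool, count=len(pairs))
    tp = np.cumsum(hits)
    k = np.arange(1, len(pairs) + 1)
    precision = tp / k
    recall = tp / gold.n_edges
    return precision, recall


def aupr(ranked: RankedEdgeList, gold: GoldStandard) -> float:
    """Step-wise area under the precision-recall curve, in [0, 1]."""
    precision, recall = pr_curve(ranked, gold)
    drecall = np.diff(np.concatenate([[0.0], recall]))
    return float(np.sum(precision * drecall))


def relative_ranks(
    ranked: RankedEdgeList, gold: GoldStandard
) -> dict[tuple[str, str], float]:
    """1-based rank of each gold edge divided by P = N(N-1)."""
    pairs = complete_ranking(ranked, gold)
    P = gold.universe
    position = {pair: k + 1 for k, pair in enumerate(pairs)}
    return {edge: position[edge] / P for edge in gold.edges}


def binned_error_by_regulator_expression(
    ranked: RankedEdgeList,
    gold: GoldStandard,
    X_ko: ExpressionMatrix,
    komap: KnockoutMap,
    n_bins: int = 7,
) -> list[dict]:
    """Relative-rank distributions binned by regulator median expression.

    Each regulator's summary statistic is the median of its expression row
    across the knock-out conditions; regulators are split into ``n_bins``
    equal-count bins (low to high expression) and every gold edge is
    assigned to its regulator's bin. Returns one record per bin with the
    member regulators and the relative ranks of their outgoing true edges.
    """
    rr = relative_ranks(ranked, gold)
    regulators = sorted({reg for reg, _ in gold.edges}, key=natural_gene_key)
    med = {
        reg: float(np.median(X_ko.values[X_ko.gene_index(reg), :]))
        for reg in regulators
    }
    # equal-count binning, ties broken by label for determinism
    ordered = sorted(regulators, key=lambda r: (med[r], natural_gene_key(r)))
    n_reg = len(ordered)
    bins: list[dict] = []
    bounds = [round(k * n_reg / n_bins) for k in range(n_bins + 1)]
    for b in range(n_bins):
        members = ordered[bounds[b] : bounds[b + 1]]
        ranks = [rr[(reg, tgt)] for reg, tgt in gold.edges if reg in set(members)]
        bins.append(
            {
                "bin": b,
                "regulators": members,
                "median_expression": [med[r] for r in members],
                "relative_ranks": sorted(ranks),
            }
        )
    return bins
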