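"""Median-corrected z-scores (MCZ) from knock-out steady states.

A regulator's knock-out should move the expression of its targets away
from wild type. Because any single wild-type profile is noisy, the
wild-type level of each gene is estimated as the *median* of its
expression over all wild-type observations *and* all single-gene
knock-out columns (sparse networks make most KO columns independent
wild-type measurements of most genes). The score of the directed edge
j -> i is the absolute deviation of gene i's expression under the KO of
gene j from that median, in units of gene i's standard deviation over the
same WT + KO columns.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .datamodel import ConfidenceMatrix, ExpressionMatrix, KnockoutMap

__all__ = [
    "WildTypeEstimate",
    "corrected_wildtype",
    "mcz_scores",
    "mcz_filter_mask",
]


@dataclass
class WildTypeEstimate:
    """Per-gene median and standard deviation over WT + KO columns."""

    gene_ids: list[str]
    median: np.ndarray
    sd: np.ndarray
    n_obs: int

    def __post_init__(self) -> None:
        self.median = np.asarray(self.median, dtype=float)
        self.sd = np.asarray(self.sd, dtype=float)
        if np.any(self.sd < 0):
            raise ValueError("standard deviations must be >= 0")


def corrected_wildtype(
    X_wt: ExpressionMatrix,
    X_ko: ExpressionMatrix,
    komap: KnockoutMap | None = None,
    exclude_self_ko: bool = False,
) -> WildTypeEstimate:
    """Median-corrected wild-type estimate over the WT and KO blocks.

    ``exclude_self_ko=True`` drops gene i's own knock-out column from its
    median/sd (the self-KO is guaranteed non-wild-type); the default keeps
    it, computing the plain median/sd over all WT and KO columns. Sample
    standard deviation (ddof=1).
    """
    if X_wt.gene_ids != X_ko.gene_ids:
        raise ValueError("WT and KO blocks must share gene order")
    pooled = np.concatenate([X_wt.values, X_ko.values], axis=1)
    n_obs = pooled.shape[1]
    if n_obs < 2:
        raise ValueError("need at least 2 WT+KO columns to estimate a sd")
    if not exclude_self_ko:
        median = np.median(pooled, axis=1)
        sd = np.std(pooled, axis=1, ddof=1)
    else:
        if komap is None:
            raise ValueError("exclude_self_ko requires a knockout map")
        n_wt = X_wt.n_conditions
        median = np.empty(X_wt.n_genes)
        sd = np.empty(X_wt.n_genes)
        for i, g in enumerate(X_wt.gene_ids):
            cols = np.ones(n_obs, dtype=bool)
            if g in komap:
                cols[n_wt + komap.column(g)] = False
            vals = pooled[i, cols]
            median[i] = np.median(vals)
            sd[i] = np.std(vals, ddof=1)
    return WildTypeEstimate(list(X_wt.gene_ids), median, sd, n_obs)


def mcz_scores(
    X_ko: ExpressionMatrix,
    komap: KnockoutMap,
    est: WildTypeEstimate,
) -> ConfidenceMatrix:
    """Confidence matrix Z(i, j) = |x_i^(KO j) - median_i| / sd_i.

    The diagonal is 0. Genes with sd_i = 0 get score 0 where the deviation
    is 0 and otherwise a sentinel one larger than the largest finite score
    in the matrix (preserves the ranking without infinities).
    """
    genes = est.gene_ids
    if X_ko.gene_ids != genes:
        raise ValueError("KO block and estimate must share gene order")
    n = len(genes)
    for g in genes:
        if g not in komap:
            raise ValueError(f"knockout map is missing gene {g!r}")
    ko_cols = np.array([komap.column(g) for g in genes])
    # deviations[i, j] = x_i under KO of gene j, minus median_i
    dev = X_ko.values[:, ko_cols] - est.median[:, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.abs(dev) / est.sd[:, None]
    degenerate = est.sd == 0
    if np.any(degenerate):
        z[degenerate, :] = 0.0
        finite_max = np.max(z[np.isfinite(z)], initial=0.0)
        sentinel_rows = np.where(degenerate)[0]
        for i in sentinel_rows:
            nz = np.abs(dev[i, :]) > 0
            z[i, nz] = finite_max + 1.0
    np.fill_diagonal(z, 0.0)
    return ConfidenceMatrix(list(genes), z)


def mcz_filter_mask(Z_mcz: ConfidenceMatrix, lower_percentile: float) -> np.ndarray:
    """Boolean mask keeping off-diagonal scores strictly above the
    ``lower_percentile``-th percentile of all off-diagonal MCZ scores.

    Used before combining MCZ with the time-series pipelines: edges in the
    lower tail of the MCZ distribution are removed from consideration.
    """
    if not (0 <= lower_percentile < 100):
        raise ValueError("lower_percentile must be in [0, 100)")
    n = Z_mcz.n_genes
    offdiag = ~np.eye(n, dtype=bool)
    if lower_percentile == 0:
        return offdiag
    cutoff = np.percentile(Z_mcz.values[offdiag], lower_percentile)
    return offdiag & (Z_mcz.values > cutoff)
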