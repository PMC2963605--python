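"""Pipeline assembly: rank-transplant combination and the bootstrap ensemble.

Confidence matrices produced by different methods live on incompatible
scales. The *rank transplant* puts matrix B onto matrix A's scale by
replacing B's k-th largest nonzero entry with A's k-th largest value,
then combines the two element-wise (sum; any monotone combination yields
the same ranking). Pipeline 2 transplants the lasso confidences onto the
tlCLR scale; pipeline 3 transplants the pipeline-2 result onto the MCZ
scale.

Pipeline 4 wraps pipeline 3 in a column bootstrap of the
response/explanatory design: each resample re-runs tlCLR + lasso +
combination against the *fixed* MCZ matrix; per-edge median ranks across
the ensemble give the final confidence, and per-edge median dynamical
parameters (zeros included, which keeps the median sparse) give the
ensemble model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata

from .datamodel import ConfidenceMatrix, DynamicalModel
from .design import ResponseDesign
from .inferelator import (
    dynamical_model_from_fits,
    fit_all_genes,
    inferelator_confidences,
    select_candidates,
)
from .tlclr import mi_matrices, tlclr_scores

__all__ = [
    "NetworkEnsemble",
    "rank_transplant_combine",
    "pipeline2",
    "pipeline3",
    "bootstrap_columns",
    "run_resampling_pipeline",
    "ensemble_medians",
]


@dataclass
class NetworkEnsemble:
    """Per-resample combined confidences and dynamical models."""

    gene_ids: list[str]
    members: list[tuple[ConfidenceMatrix, DynamicalModel]]
    seed: int

    @property
    def n_resamples(self) -> int:
        return len(self.members)


def _sorted_offdiag_desc(Z: ConfidenceMatrix) -> np.ndarray:
    vals = Z.offdiag_values()
    return np.sort(vals)[::-1]


def rank_transplant_combine(
    A: ConfidenceMatrix, B: ConfidenceMatrix
) -> ConfidenceMatrix:
    """Combine B with reference A after transplanting A's values onto B's ranks.

    The k-th largest nonzero entry of B (ties broken by (regulator, target)
    index) receives the k-th largest off-diagonal value of A; if B has more
    nonzero entries than A has values at that depth, the remainder get A's
    smallest positive value (or 0 when A has none). The result is
    A + B' element-wise with a zero diagonal.
    """
    if A.gene_ids != B.gene_ids:
        raise ValueError("matrices must share the gene universe")
    n = A.n_genes
    offdiag = ~np.eye(n, dtype=bool)
    ii, jj = np.nonzero(offdiag & (B.values != 0))
    scores = B.values[ii, jj]
    order = np.lexsort((ii, jj, -scores))
    a_sorted = _sorted_offdiag_desc(A)
    positive = a_sorted[a_sorted > 0]
    fallback = float(positive[-1]) if positive.size else 0.0
    B_prime = np.zeros_like(B.values)
    for rank, k in enumerate(order):
        value = a_sorted[rank] if rank < a_sorted.size else fallback
        B_prime[ii[k], jj[k]] = value
    combined = A.values + B_prime
    return ConfidenceMatrix(list(A.gene_ids), combined)


def pipeline2(Z_tlclr: ConfidenceMatrix, Z_inf: ConfidenceMatrix) -> ConfidenceMatrix:
    """tlCLR-Inferelator combination (tlCLR is the reference scale)."""
    return rank_transplant_combine(Z_tlclr, Z_inf)


def pipeline3(Z_p2: ConfidenceMatrix, Z_mcz: ConfidenceMatrix) -> ConfidenceMatrix:
    """Combine the tlCLR-Inferelator result with MCZ (MCZ is the reference)."""
    return rank_transplant_combine(Z_mcz, Z_p2)


def bootstrap_columns(rd: ResponseDesign, seed: int) -> ResponseDesign:
    """Resample design columns with replacement; Y/X pairing preserved."""
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, rd.n_obs, size=rd.n_obs)
    return rd.subset_columns(idx)


def _single_pipeline3(
    rd: ResponseDesign,
    Z_mcz: ConfidenceMatrix,
    mcz_mask: np.ndarray | None,
    K: int,
    n_bins: int,
    k_folds: int,
    s_grid,
    seed: int,
) -> tuple[ConfidenceMatrix, DynamicalModel]:
    mi = mi_matrices(rd, n_bins=n_bins)
    Z_tl = tlclr_scores(mi.M_dyn, mi.M_stat, rd.gene_ids)
    cand = select_candidates(Z_tl, mcz_mask, K)
    fits, mean, sd = fit_all_genes(rd, cand, k_folds=k_folds, s_grid=s_grid, seed=seed)
    Z_inf = inferelator_confidences(fits, rd.gene_ids)
    Z_p2 = pipeline2(Z_tl, Z_inf)
    Z_p3 = pipeline3(Z_p2, Z_mcz)
    model = dynamical_model_from_fits(fits, rd.gene_ids, rd.alpha, mean, sd)
    return Z_p3, model


def run_resampling_pipeline(
    rd: ResponseDesign,
    Z_mcz: ConfidenceMatrix,
    mcz_mask: np.ndarray | None = None,
    M: int = 200,
    K: int = 10,
    n_bins: int = 10,
    k_folds: int = 10,
    s_grid=None,
    seed: int = 0,
    identity_first: bool = False,
) -> NetworkEnsemble:
    """Bootstrap ensemble of pipeline-3 runs against the fixed MCZ matrix.

    Member m uses the deterministic seed ``seed + m``. With
    ``identity_first=True`` the first member uses the original (unresampled)
    design — useful for degenerate-ensemble checks.
    """
    if M < 1:
        raise ValueError("M must be >= 1")
    members = []
    for m in range(M):
        if identity_first and m == 0:
            rd_m = rd
        else:
            rd_m = bootstrap_columns(rd, seed + m)
        members.append(
            _single_pipeline3(
                rd_m, Z_mcz, mcz_mask, K, n_bins, k_folds, s_grid, seed + m
            )
        )
    return NetworkEnsemble(list(rd.gene_ids), members, seed)


def ensemble_medians(
    E: NetworkEnsemble, use_scores: bool = False
) -> tuple[ConfidenceMatrix, DynamicalModel]:
    """Median rank (default) or median transplanted score across the ensemble.

    Each member's off-diagonal entries are ranked (1 = highest confidence,
    ties get average ranks); the final confidence of an edge is
    P + 1 - median(rank), a positive score whose ordering follows the
    median rank. Dynamical parameters are medianed entry-wise across
    members, zeros included.
    """
    genes = E.gene_ids
    n = len(genes)
    offdiag = ~np.eye(n, dtype=bool)
    P = n * (n - 1)
    if use_scores:
        stack = np.stack([Z.values for Z, _ in E.members])
        Z_med = np.median(stack, axis=0)
    else:
        ranks = []
        for Z, _ in E.members:
            r = rankdata(-Z.values[offdiag], method="average")
            ranks.append(r)
        med = np.median(np.stack(ranks), axis=0)
        Z_med = np.zeros((n, n))
        Z_med[offdiag] = P + 1 - med
    beta_med = np.median(np.stack([m.beta for _, m in E.members]), axis=0)
    bias_med = np.median(np.stack([m.bias for _, m in E.members]), axis=0)
    h_med = np.median(np.stack([m.h for _, m in E.members]), axis=0)
    # regressor statistics vary slightly across resamples; median them too
    mean_med = np.median(np.stack([m.regressor_mean for _, m in E.members]), axis=0)
    sd_med = np.median(np.stack([m.regressor_sd for _, m in E.members]), axis=0)
    model = DynamicalModel(
        gene_ids=list(genes),
        beta=beta_med,
        bias=bias_med,
        h=h_med,
        alpha=E.members[0][1].alpha,
        regressor_mean=mean_med,
        regressor_sd=sd_med,
    )
    return ConfidenceMatrix(list(genes), Z_med), model
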