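"""Shared domain types for gene-regulatory-network inference.

Conventions used throughout the package:

* Genes are labelled ``G1 .. GN`` (DREAM4 style); all in-memory indexing is
  0-based and file formats carry the 1-based labels only.
* Confidence matrices are oriented rows = targets, columns = regulators:
  entry ``(i, j)`` scores the directed edge *regulator j -> target i*.
  Self-edges (the diagonal) are excluded from every ranking.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "ExpressionMatrix",
    "TimeSeriesSet",
    "TimeSeriesExperiment",
    "KnockoutMap",
    "ConfidenceMatrix",
    "GoldStandard",
    "DynamicalModel",
    "RankedEdgeList",
    "default_gene_ids",
]


def default_gene_ids(n: int) -> list[str]:
    """DREAM4-style gene labels ``G1 .. Gn``."""
    return [f"G{k + 1}" for k in range(n)]


def _check_unique(labels: Sequence[str], what: str) -> None:
    if len(set(labels)) != len(labels):
        raise ValueError(f"{what} must be unique")


@dataclass
class ExpressionMatrix:
    """Genes x conditions matrix of nonnegative expression values.

    Parameters
    ----------
    gene_ids : ordered gene labels (rows).
    condition_ids : ordered condition labels (columns).
    values : ``(n_genes, n_conditions)`` array, finite, no missing entries.
    """

    gene_ids: list[str]
    condition_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.gene_ids = list(self.gene_ids)
        self.condition_ids = list(self.condition_ids)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("expression values must be 2-D")
        if self.values.shape != (len(self.gene_ids), len(self.condition_ids)):
            raise ValueError(
                f"shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.condition_ids)} conditions"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("expression values must be finite")
        _check_unique(self.gene_ids, "gene_ids")
        _check_unique(self.condition_ids, "condition_ids")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_conditions(self) -> int:
        return len(self.condition_ids)

    def gene_index(self, gene: str) -> int:
        return self.gene_ids.index(gene)


@dataclass
class TimeSeriesExperiment:
    """One evenly sampled observation block.

    ``matrix`` is genes x timepoints; ``time_stamps`` strictly increasing
    with constant spacing.
    """

    time_stamps: np.ndarray
    matrix: np.ndarray

    def __post_init__(self) -> None:
        self.time_stamps = np.asarray(self.time_stamps, dtype=float)
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.time_stamps.ndim != 1 or self.time_stamps.size < 2:
            raise ValueError("an experiment needs at least 2 time points")
        if self.matrix.shape[1] != self.time_stamps.size:
            raise ValueError("matrix columns must match time stamps")
        diffs = np.diff(self.time_stamps)
        if np.any(diffs <= 0):
            raise ValueError("time stamps must be strictly increasing")
        if not np.allclose(diffs, diffs[0], rtol=1e-9, atol=1e-9):
            raise ValueError(
                f"non-constant time spacing {diffs.tolist()} within one experiment"
            )

    @property
    def dt(self) -> float:
        return float(self.time_stamps[1] - self.time_stamps[0])

    @property
    def n_timepoints(self) -> int:
        return int(self.time_stamps.size)


@dataclass
class TimeSeriesSet:
    """Ordered collection of time-series experiments over one gene universe.

    Perturbation and relaxation phases are stored as separate experiments.
    """

    gene_ids: list[str]
    experiments: list[TimeSeriesExperiment]

    def __post_init__(self) -> None:
        self.gene_ids = list(self.gene_ids)
        _check_unique(self.gene_ids, "gene_ids")
        for exp in self.experiments:
            if exp.matrix.shape[0] != len(self.gene_ids):
                raise ValueError("experiment gene dimension mismatch")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    def all_columns(self) -> np.ndarray:
        """All time-point observations concatenated, genes x total points."""
        return np.concatenate([e.matrix for e in self.experiments], axis=1)


@dataclass
class KnockoutMap:
    """Bijection from gene id to the KO (or KD) condition column index."""

    gene_to_condition: dict[str, int]

    def __post_init__(self) -> None:
        cols = list(self.gene_to_condition.values())
        if len(set(cols)) != len(cols):
            raise ValueError("knockout map must be bijective over its genes")

    def column(self, gene: str) -> int:
        try:
            return self.gene_to_condition[gene]
        except KeyError:
            raise KeyError(f"gene {gene!r} has no knock-out condition") from None

    def __contains__(self, gene: str) -> bool:
        return gene in self.gene_to_condition

    def __len__(self) -> int:
        return len(self.gene_to_condition)


@dataclass
class ConfidenceMatrix:
    """N x N edge confidences; entry (i, j) = regulator j -> target i.

    Self-edges carry score 0 and are excluded from rankings.
    """

    gene_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.gene_ids = list(self.gene_ids)
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.gene_ids)
        if self.values.shape != (n, n):
            raise ValueError("confidence matrix must be N x N")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("confidence scores must be finite")
        np.fill_diagonal(self.values, 0.0)

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    def offdiag_values(self) -> np.ndarray:
        """Off-diagonal scores as a flat vector (row-major)."""
        n = self.n_genes
        mask = ~np.eye(n, dtype=bool)
        return self.values[mask]


@dataclass
class GoldStandard:
    """True directed topology: set of (regulator, target) label pairs.

    ``universe`` is P = N(N-1), the number of possible ordered non-self
    pairs — the denominator of the relative rank.
    """

    gene_ids: list[str]
    edges: set[tuple[str, str]]

    def __post_init__(self) -> None:
        self.gene_ids = list(self.gene_ids)
        known = set(self.gene_ids)
        for reg, tgt in self.edges:
            if reg == tgt:
                raise ValueError(f"self-edge {reg}->{tgt} in gold standard")
            if reg not in known or tgt not in known:
                raise ValueError(f"edge {reg}->{tgt} outside gene universe")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def universe(self) -> int:
        n = len(self.gene_ids)
        return n * (n - 1)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def adjacency_pattern(self) -> np.ndarray:
        """Boolean matrix, entry (i, j) True iff regulator j -> target i."""
        idx = {g: k for k, g in enumerate(self.gene_ids)}
        out = np.zeros((self.n_genes, self.n_genes), dtype=bool)
        for reg, tgt in self.edges:
            out[idx[tgt], idx[reg]] = True
        return out


@dataclass
class DynamicalModel:
    """Sparse linear ODE parameterization dx_i/dt = sum_j beta_ij u_j + beta_i0 - alpha x_i.

    ``beta`` is expressed on *standardized* regulators u_j; ``regressor_mean``
    and ``regressor_sd`` hold the per-gene statistics needed to map raw
    expression onto that scale. ``h`` is the cross-validated explanatory
    power of each gene's model, clipped to [0, 1].
    """

    gene_ids: list[str]
    beta: np.ndarray
    bias: np.ndarray
    h: np.ndarray
    alpha: float
    regressor_mean: np.ndarray
    regressor_sd: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.gene_ids)
        self.beta = np.asarray(self.beta, dtype=float)
        self.bias = np.asarray(self.bias, dtype=float)
        self.h = np.clip(np.asarray(self.h, dtype=float), 0.0, 1.0)
        self.regressor_mean = np.asarray(self.regressor_mean, dtype=float)
        self.regressor_sd = np.asarray(self.regressor_sd, dtype=float)
        if self.beta.shape != (n, n):
            raise ValueError("beta must be N x N")
        for vec, name in [
            (self.bias, "bias"),
            (self.h, "h"),
            (self.regressor_mean, "regressor_mean"),
            (self.regressor_sd, "regressor_sd"),
        ]:
            if vec.shape != (n,):
                raise ValueError(f"{name} must have length N")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)


@dataclass
class RankedEdgeList:
    """Directed edges sorted by non-increasing confidence.

    Ties are broken by (regulator label, target label) natural order so the
    list is deterministic. No duplicates, no self-edges.
    """

    edges: list[tuple[str, str, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen = set()
        prev = np.inf
        for reg, tgt, score in self.edges:
            if reg == tgt:
                raise ValueError(f"self-edge {reg}->{tgt} in ranked list")
            if (reg, tgt) in seen:
                raise ValueError(f"duplicate edge {reg}->{tgt}")
            seen.add((reg, tgt))
            if score > prev + 1e-12:
                raise ValueError("ranked edge list scores must be non-increasing")
            prev = score

    def __len__(self) -> int:
        return len(self.edges)

    def __iter__(self):
        return iter(self.edges)


def natural_gene_key(label: str):
    """Sort key treating 'G10' > 'G2' (numeric suffix aware)."""
    if label[:1] in ("G", "g") and label[1:].isdigit():
        return (0, int(label[1:]), label)
    return (1, 0, label)
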