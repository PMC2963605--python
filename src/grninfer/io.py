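"""Readers and writers for DREAM4-style tab-delimited tables.

Three dialects are supported:

* steady-state tables — first row gene ids, each subsequent row one
  condition (the file is conditions x genes; in memory everything is
  genes x conditions);
* time-series tables — header ``Time`` + gene ids; a decrease in the time
  value starts a new experiment block;
* 3-column edge files — ``regulator<TAB>target<TAB>value`` for both gold
  standards (value in {0, 1}) and ranked predictions (value = confidence).
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import numpy as np

from .datamodel import (
    ConfidenceMatrix,
    ExpressionMatrix,
    GoldStandard,
    KnockoutMap,
    RankedEdgeList,
    TimeSeriesExperiment,
    TimeSeriesSet,
)

__all__ = [
    "read_steady_state_table",
    "write_steady_state_table",
    "read_time_series_table",
    "write_time_series_table",
    "write_ranked_edges",
    "ranked_edges_from_confidence",
    "read_ranked_edges",
    "read_gold_standard",
    "write_gold_standard",
]


class ParseError(ValueError):
    """Malformed input file; message names the offending line."""


def _parse_float(token: str, path, lineno: int) -> float:
    try:
        return float(token)
    except ValueError:
        raise ParseError(
            f"{path}: line {lineno}: non-numeric value {token!r}"
        ) from None


def read_steady_state_table(
    path, knockout_semantics: bool = False
) -> ExpressionMatrix | tuple[ExpressionMatrix, KnockoutMap]:
    """Read a conditions-in-rows steady-state table.

    With ``knockout_semantics=True`` row k is interpreted as the
    knock-out (or knock-down) of gene k, and a :class:`KnockoutMap` is
    returned alongside the matrix.
    """
    path = Path(path)
    lines = [ln for ln in path.read_text().splitlines() if ln.strip() != ""]
    if not lines:
        raise ParseError(f"{path}: empty file")
    gene_ids = lines[0].rstrip("\n").split("\t")
    n_genes = len(gene_ids)
    rows = []
    for lineno, line in enumerate(lines[1:], start=2):
        fields = line.split("\t")
        if len(fields) != n_genes:
            raise ParseError(
                f"{path}: line {lineno}: expected {n_genes} fields, got {len(fields)}"
            )
        rows.append([_parse_float(tok, path, lineno) for tok in fields])
    values = np.asarray(rows, dtype=float).T  # genes x conditions
    if knockout_semantics:
        if len(rows) != n_genes:
            raise ParseError(
                f"{path}: knock-out table needs one row per gene "
                f"({n_genes} genes, {len(rows)} rows)"
            )
        condition_ids = [f"KO_{g}" for g in gene_ids]
        em = ExpressionMatrix(gene_ids, condition_ids, values)
        komap = KnockoutMap({g: k for k, g in enumerate(gene_ids)})
        return em, komap
    condition_ids = [f"c{k + 1}" for k in range(len(rows))]
    return ExpressionMatrix(gene_ids, condition_ids, values)


def write_steady_state_table(em: ExpressionMatrix, path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write("\t".join(em.gene_ids) + "\n")
        for col in range(em.n_conditions):
            fh.write("\t".join(repr(float(v)) for v in em.values[:, col]) + "\n")


def read_time_series_table(path) -> TimeSeriesSet:
    """Read a multi-experiment time-series table.

    Header is ``Time`` followed by gene ids; a time value lower than or
    equal to its predecessor starts a new experiment block. Constant
    spacing within each block is enforced.
    """
    path = Path(path)
    lines = [ln for ln in path.read_text().splitlines() if ln.strip() != ""]
    if not lines:
        raise ParseError(f"{path}: empty file")
    header = lines[0].split("\t")
    if not header or header[0].strip().lower() != "time":
        raise ParseError(f"{path}: line 1: first column must be 'Time'")
    gene_ids = header[1:]
    n_fields = len(header)
    blocks: list[tuple[list[float], list[list[float]]]] = []
    prev_t = None
    for lineno, line in enumerate(lines[1:], start=2):
        fields = line.split("\t")
        if len(fields) != n_fields:
            raise ParseError(
                f"{path}: line {lineno}: expected {n_fields} fields, got {len(fields)}"
            )
        t = _parse_float(fields[0], path, lineno)
        vals = [_parse_float(tok, path, lineno) for tok in fields[1:]]
        if prev_t is None or t <= prev_t:
            blocks.append(([], []))
        blocks[-1][0].append(t)
        blocks[-1][1].append(vals)
        prev_t = t
    experiments = []
    for times, rows in blocks:
        matrix = np.asarray(rows, dtype=float).T
        experiments.append(TimeSeriesExperiment(np.asarray(times), matrix))
    return TimeSeriesSet(gene_ids, experiments)


def write_time_series_table(ts: TimeSeriesSet, path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write("Time\t" + "\t".join(ts.gene_ids) + "\n")
        for exp in ts.experiments:
            for k, t in enumerate(exp.time_stamps):
                row = "\t".join(repr(float(v)) for v in exp.matrix[:, k])
                fh.write(f"{repr(float(t))}\t{row}\n")


def ranked_edges_from_confidence(
    Z: ConfidenceMatrix, max_edges: int | None = None
) -> RankedEdgeList:
    """Sort off-diagonal entries of Z into a deterministic ranked edge list.

    Descending score; ties broken by (regulator index, target index) so the
    ordering is invariant to the score scale.
    """
    n = Z.n_genes
    ii, jj = np.nonzero(~np.eye(n, dtype=bool))
    scores = Z.values[ii, jj]
    # lexsort keys: last key is primary
    order = np.lexsort((ii, jj, -scores))
    edges = [
        (Z.gene_ids[jj[k]], Z.gene_ids[ii[k]], float(scores[k])) for k in order
    ]
    if max_edges is not None:
        edges = edges[:max_edges]
    return RankedEdgeList(edges)


def write_ranked_edges(
    Z: ConfidenceMatrix, path, max_edges: int | None = None
) -> RankedEdgeList:
    """Write Z as a ranked prediction file ``Gj<TAB>Gi<TAB>score``."""
    ranked = ranked_edges_from_confidence(Z, max_edges)
    path = Path(path)
    with path.open("w") as fh:
        for reg, tgt, score in ranked:
            fh.write(f"{reg}\t{tgt}\t{repr(score)}\n")
    return ranked


def read_ranked_edges(path) -> RankedEdgeList:
    path = Path(path)
    edges = []
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if line.strip() == "":
            continue
        fields = line.split("\t")
        if len(fields) != 3:
            raise ParseError(f"{path}: line {lineno}: expected 3 fields")
        reg, tgt, tok = fields
        edges.append((reg, tgt, _parse_float(tok, path, lineno)))
    return RankedEdgeList(edges)


def read_gold_standard(path, gene_ids: Sequence[str] | None = None) -> GoldStandard:
    """Read a 3-column gold standard ``Gj<TAB>Gi<TAB>{0,1}``.

    Pairs flagged 1 are edges; flagged 0 or absent are non-edges. The gene
    universe defaults to the ids seen in the file (sorted naturally); pass
    ``gene_ids`` when the file may omit isolated genes.
    """
    from .datamodel import natural_gene_key

    path = Path(path)
    edges = set()
    seen: set[str] = set()
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if line.strip() == "":
            continue
        fields = line.split("\t")
        if len(fields) != 3:
            raise ParseError(f"{path}: line {lineno}: expected 3 fields")
        reg, tgt, flag = fields
        seen.add(reg)
        seen.add(tgt)
        if flag.strip() not in ("0", "1"):
            raise ParseError(
                f"{path}: line {lineno}: edge flag must be 0 or 1, got {flag!r}"
            )
        if flag.strip() == "1":
            edges.add((reg, tgt))
    if gene_ids is None:
        gene_ids = sorted(seen, key=natural_gene_key)
    return GoldStandard(list(gene_ids), edges)


def write_gold_standard(gold: GoldStandard, path, include_zeros: bool = False) -> None:
    from .datamodel import natural_gene_key

    path = Path(path)
    key = lambda e: (natural_gene_key(e[0]), natural_gene_key(e[1]))
    with path.open("w") as fh:
        for reg, tgt in sorted(gold.edges, key=key):
            fh.write(f"{reg}\t{tgt}\t1\n")
        if include_zeros:
            present = gold.edges
            for reg in gold.gene_ids:
                for tgt in gold.gene_ids:
                    if reg != tgt and (reg, tgt) not in present:
                        fh.write(f"{reg}\t{tgt}\t0\n")
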