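"""Readers and writers for the pipeline's flat-file artifacts.

All formats are UTF-8 TSV with Unix newlines and a header row.  Writers
are deterministic (identical inputs give byte-identical files) and
numeric values are serialized with full ``repr`` round-trip precision, so
read-after-write is exact.

Expression matrix layout::

    gene_id  [rna_type]  SAMPLE1  SAMPLE2  ...
    CDH1     mRNA        12.3     0.0      ...

The ``rna_type`` column is optional: a whole file may instead declare one
RNA type for all its rows (the TCGA-style per-class profile files).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .exceptions import ParseError, ValidationError
from .expression import RNA_TYPES, ExpressionMatrix
from .genesets import GeneSet, read_gmt, write_gmt  # noqa: F401  (re-export)
from .network import RegulatoryGraph
from .triplets import Triplet

TYPE_COLUMN = "rna_type"


def _is_number(s) -> bool:
    try:
        return not np.isnan(float(s))
    except ValueError:
        return False


# ---------------------------------------------------------------------------
# expression matrices
# ---------------------------------------------------------------------------

def read_expression(path, rna_type: str = "from-column") -> ExpressionMatrix:
    """Read a TSV expression matrix.

    ``rna_type`` is either ``"from-column"`` (the second column carries a
    per-row type) or one of ``{"mRNA", "lncRNA", "miRNA"}`` applied to all
    rows.  Non-numeric cells raise :class:`ParseError` naming the gene and
    sample; duplicate gene ids raise :class:`ValidationError`.
    """
    if rna_type != "from-column" and rna_type not in RNA_TYPES:
        raise ValidationError(
            f"rna_type must be 'from-column' or one of {RNA_TYPES}")
    # an optional leading "#scale=log" line records the transform state
    log_transformed = False
    skiprows = 0
    try:
        with open(path, encoding="utf-8") as fh:
            first = fh.readline()
    except OSError as exc:
        raise ValidationError(f"{path}: {exc}") from exc
    if first.startswith("#scale="):
        log_transformed = first.strip() == "#scale=log"
        skiprows = 1
    try:
        raw = pd.read_csv(path, sep="\t", dtype=str, header=0,
                          skiprows=skiprows, keep_default_na=False)
    except pd.errors.EmptyDataError:
        raise ValidationError(f"{path}: empty expression file") from None
    if raw.shape[0] == 0:
        raise ValidationError(f"{path}: expression file has no data rows")

    gene_col = raw.columns[0]
    gene_ids = raw[gene_col].tolist()
    dup = raw[gene_col][raw[gene_col].duplicated()].unique()
    if len(dup):
        raise ValidationError(f"{path}: duplicate gene id(s): {list(dup)[:5]}")

    if rna_type == "from-column":
        if raw.shape[1] < 2 or raw.columns[1] != TYPE_COLUMN:
            raise ValidationError(
                f"{path}: expected second column {TYPE_COLUMN!r} "
                "when rna_type='from-column'")
        types = raw[TYPE_COLUMN].tolist()
        value_cols = raw.columns[2:]
    else:
        types = [rna_type] * len(gene_ids)
        value_cols = (raw.columns[2:] if raw.shape[1] > 1
                      and raw.columns[1] == TYPE_COLUMN else raw.columns[1:])
    if len(value_cols) == 0:
        raise ValidationError(f"{path}: no sample columns")

    values = {}
    for col in value_cols:
        cells = raw[col].tolist()
        try:
            # builtin float() is correctly rounded, so repr round-trips
            values[col] = np.array([float(v) for v in cells], dtype=float)
        except ValueError:
            i = next(k for k, v in enumerate(cells)
                     if not _is_number(v))
            raise ParseError(
                f"{path}: non-numeric value {cells[i]!r} for gene "
                f"{gene_ids[i]!r} in sample column {col!r}",
                row=gene_ids[i], column=str(col)) from None
        if np.isnan(values[col]).any():
            i = int(np.flatnonzero(np.isnan(values[col]))[0])
            raise ParseError(
                f"{path}: non-numeric value {cells[i]!r} for gene "
                f"{gene_ids[i]!r} in sample column {col!r}",
                row=gene_ids[i], column=str(col))
    df = pd.DataFrame(values, index=pd.Index(gene_ids, name="gene_id"))
    return ExpressionMatrix(df, pd.Series(types, index=df.index),
                            log_transformed)


def write_expression(matrix: ExpressionMatrix, path) -> None:
    """Write a matrix with the per-row ``rna_type`` column.

    Values use ``repr`` precision so that read-after-write is exact.
    """
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        if matrix.log_transformed:
            fh.write("#scale=log\n")
        fh.write("\t".join(["gene_id", TYPE_COLUMN, *map(str, matrix.sample_ids)]))
        fh.write("\n")
        arr = matrix.values.to_numpy()
        for i, gid in enumerate(matrix.gene_ids):
            row = "\t".join(repr(float(v)) for v in arr[i])
            fh.write(f"{gid}\t{matrix.gene_types.iloc[i]}\t{row}\n")


# ---------------------------------------------------------------------------
# edge lists
# ---------------------------------------------------------------------------

_EDGE_HEADER = ["gene_a", "type_a", "gene_b", "type_b", "adj_r2"]


def write_edges(graph: RegulatoryGraph, path) -> None:
    """Serialize the network as a canonical TSV edge list.

    Within each edge the endpoints are ordered lexicographically, rows are
    sorted by (gene_a, gene_b), so output is byte-stable.  Discovery
    provenance is not serialized; read-after-write reproduces the edge
    set, vertex types and adjusted R^2 values exactly.
    """
    types = graph.vertices()
    rows = sorted((a, b, r2) for a, b, r2 in graph.edges())
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("\t".join(_EDGE_HEADER) + "\n")
        for a, b, r2 in rows:
            fh.write(f"{a}\t{types[a]}\t{b}\t{types[b]}\t{float(r2)!r}\n")


def read_edges(path) -> RegulatoryGraph:
    """Read an edge list written by :func:`write_edges`."""
    graph = RegulatoryGraph()
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != _EDGE_HEADER:
            raise ValidationError(
                f"{path}: bad edge-list header {header!r}")
        for lineno, raw in enumerate(fh, start=2):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) != 5:
                raise ValidationError(
                    f"{path}:{lineno}: expected 5 fields, got {len(fields)}")
            a, ta, b, tb, r2 = fields
            if ta not in RNA_TYPES or tb not in RNA_TYPES:
                raise ValidationError(
                    f"{path}:{lineno}: unknown RNA type token "
                    f"{ta!r} / {tb!r}")
            try:
                r2val = float(r2)
            except ValueError:
                raise ParseError(
                    f"{path}:{lineno}: non-numeric adj_r2 {r2!r}",
                    line=lineno) from None
            graph.add_relation(a, b, ta, tb, r2val)
    return graph


# ---------------------------------------------------------------------------
# triplet tables
# ---------------------------------------------------------------------------

_TRIPLET_HEADER = ["mrna", "lncrna", "mirna"]


def write_triplets(triplets: list[Triplet], path) -> None:
    """One row per triplet, sorted lexicographically; header always present."""
    rows = sorted((str(t.mrna), str(t.lncrna), str(t.mirna)) for t in triplets)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("\t".join(_TRIPLET_HEADER) + "\n")
        for row in rows:
            fh.write("\t".join(row) + "\n")


def read_triplets(path) -> list[Triplet]:
    """Read a triplet table written by :func:`write_triplets`."""
    out = []
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != _TRIPLET_HEADER:
            raise ValidationError(f"{path}: bad triplet header {header!r}")
        for lineno, raw in enumerate(fh, start=2):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) != 3:
                raise ValidationError(
                    f"{path}:{lineno}: expected 3 fields, got {len(fields)}")
            out.append(Triplet(*fields))
    return out
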