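"""Expression-data conditioning ahead of network inference.

RPKM profiles contain exact zeros that forbid a log transform; each zero
is replaced by the minimum nonzero value of its own sample (column), a
per-sample floor that preserves every observed value.  miRNA profiles are
pulled out of the noncoding compendium by gene-symbol prefix, and the
three per-class matrices are merged into the single combined matrix the
per-target regressions run over.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .exceptions import ValidationError
from .expression import ExpressionMatrix

#: Symbol prefixes that identify miRNA rows in human noncoding profiles.
DEFAULT_MIRNA_PREFIXES = ("hsa-mir", "hsa-let", "mir", "let-7")


def replace_zeros(m: ExpressionMatrix) -> ExpressionMatrix:
    """Replace each zero with its sample's minimum nonzero value.

    Operates column-by-column; nonzero entries are untouched.  A sample
    with no nonzero value at all has no defined floor and is rejected.
    """
    if m.log_transformed:
        raise ValidationError("replace_zeros expects RPKM-scale values")
    vals = m.values.to_numpy(dtype=float).copy()
    zero = vals == 0.0
    all_zero = zero.all(axis=0)
    if all_zero.any():
        bad = [m.sample_ids[j] for j in np.flatnonzero(all_zero)]
        raise ValidationError(
            f"sample(s) with all-zero expression, no nonzero minimum: {bad}")
    with np.errstate(invalid="ignore"):
        col_min = np.where(zero, np.inf, vals).min(axis=0)
    vals = np.where(zero, col_min[None, :], vals)
    out = pd.DataFrame(vals, index=m.values.index, columns=m.values.columns)
    return ExpressionMatrix(out, m.gene_types.copy(), m.log_transformed)


def log_transform(m: ExpressionMatrix, base: float = 2.0) -> ExpressionMatrix:
    """Elementwise log to the given base; values must be strictly positive."""
    if base <= 0 or base == 1.0:
        raise ValidationError("log base must be positive and != 1")
    if m.log_transformed:
        raise ValidationError("matrix is already log-transformed")
    vals = m.values.to_numpy(dtype=float)
    if (vals <= 0).any():
        i, j = np.argwhere(vals <= 0)[0]
        raise ValidationError(
            f"nonpositive value {vals[i, j]} at gene {m.gene_ids[i]!r}, "
            f"sample {m.sample_ids[j]!r}; run replace_zeros first")
    out = pd.DataFrame(np.log(vals) / np.log(base),
                       index=m.values.index, columns=m.values.columns)
    return ExpressionMatrix(out, m.gene_types.copy(), log_transformed=True)


def select_mirna_by_symbol(noncoding: ExpressionMatrix,
                           patterns=DEFAULT_MIRNA_PREFIXES
                           ) -> ExpressionMatrix:
    """Row subset whose symbol starts with any pattern (case-insensitive).

    Matching rows are relabeled type miRNA.  Zero matches is not an error
    — a warning is issued and an empty matrix returned — because the
    right prefixes depend on the annotation source.
    """
    pats = tuple(p.lower() for p in patterns)
    mask = [any(str(g).lower().startswith(p) for p in pats)
            for g in noncoding.gene_ids]
    if not any(mask):
        warnings.warn("no gene symbols matched the miRNA patterns "
                      f"{list(patterns)}; returning an empty matrix")
    sub = noncoding.values.loc[mask].copy()
    types = pd.Series("miRNA", index=sub.index, dtype=object)
    return ExpressionMatrix(sub, types, noncoding.log_transformed)


def combine(mrna: ExpressionMatrix, lnc: ExpressionMatrix,
            mirna: ExpressionMatrix) -> ExpressionMatrix:
    """Stack the three per-class matrices over a shared sample set.

    Columns are aligned to a canonical (lexicographically sorted) sample
    order, so the result does not depend on the column order of any
    input.  Sample sets must coincide and gene ids must be disjoint.
    """
    mats = (mrna, lnc, mirna)
    flags = {m.log_transformed for m in mats}
    if len(flags) != 1:
        raise ValidationError("cannot combine matrices on different scales")
    sample_sets = [set(m.sample_ids) for m in mats]
    ref = sample_sets[0]
    for other, name in zip(sample_sets[1:], ("lncRNA", "miRNA")):
        if other != ref:
            diff = sorted(ref ^ other)
            raise ValidationError(
                f"sample sets differ (mRNA vs {name}); "
                f"symmetric difference: {diff[:10]}")
    seen: dict = {}
    for m in mats:
        for g in m.gene_ids:
            if g in seen:
                raise ValidationError(f"gene id {g!r} appears in more than "
                                      "one input matrix")
            seen[g] = True
    order = sorted(ref)
    values = pd.concat([m.values.loc[:, order] for m in mats], axis=0)
    types = pd.concat([m.gene_types for m in mats])
    return ExpressionMatrix(values, types, mats[0].log_transformed)


def preprocess(mrna: ExpressionMatrix, lnc: ExpressionMatrix,
               mirna: ExpressionMatrix | None = None, *,
               noncoding: ExpressionMatrix | None = None,
               mirna_patterns=DEFAULT_MIRNA_PREFIXES,
               log_base: float = 2.0,
               apply_log: bool = True) -> ExpressionMatrix:
    """Full conditioning chain: zeros -> log -> combine.

    Either pass a ready ``mirna`` matrix, or a ``noncoding`` compendium
    from which miRNA rows are selected by symbol prefix.
    """
    if mirna is None:
        if noncoding is None:
            raise ValidationError("provide either mirna or noncoding")
        mirna = select_mirna_by_symbol(noncoding, mirna_patterns)
    stages = []
    for m in (mrna, lnc, mirna):
        m = replace_zeros(m)
        if apply_log:
            m = log_transform(m, base=log_base)
        stages.append(m)
    return combine(*stages)
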