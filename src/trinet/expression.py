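"""The genes-by-samples expression container shared by every pipeline stage.

An :class:`ExpressionMatrix` holds nonnegative abundances (RPKM-like before
the log transform) for genes of three RNA classes — protein-coding mRNA,
long noncoding RNA (lncRNA) and microRNA (miRNA) — measured over a shared
set of samples.  A boolean flag records whether the values are on the log
scale; preprocessing flips it exactly once.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import ValidationError

#: The RNA classes the integrative network distinguishes.
RNA_TYPES = ("mRNA", "lncRNA", "miRNA")


@dataclass
class ExpressionMatrix:
    """Genes x samples expression values with a per-gene RNA type.

    Parameters
    ----------
    values : pandas.DataFrame
        Rows indexed by unique gene identifiers, columns by unique sample
        identifiers.  Entries must be finite, and nonnegative unless
        ``log_transformed`` is True.
    gene_types : pandas.Series
        RNA type per gene, one of ``{"mRNA", "lncRNA", "miRNA"}``, indexed
        like ``values``.
    log_transformed : bool
        Whether a log transform has been applied to ``values``.
    """

    values: pd.DataFrame
    gene_types: pd.Series
    log_transformed: bool = field(default=False)

    def __post_init__(self):
        if not isinstance(self.values, pd.DataFrame):
            self.values = pd.DataFrame(self.values)
        if not isinstance(self.gene_types, pd.Series):
            self.gene_types = pd.Series(
                list(self.gene_types), index=self.values.index, dtype=object
            )
        if self.values.index.has_duplicates:
            dups = self.values.index[self.values.index.duplicated()].unique()
            raise ValidationError(f"duplicate gene ids: {list(dups)[:5]}")
        if self.values.columns.has_duplicates:
            dups = self.values.columns[self.values.columns.duplicated()].unique()
            raise ValidationError(f"duplicate sample ids: {list(dups)[:5]}")
        if not self.gene_types.index.equals(self.values.index):
            try:
                self.gene_types = self.gene_types.reindex(self.values.index)
            except Exception as exc:  # pragma: no cover - defensive
                raise ValidationError("gene_types index mismatch") from exc
            if self.gene_types.isna().any():
                missing = self.gene_types.index[self.gene_types.isna()]
                raise ValidationError(f"missing RNA type for genes: {list(missing)[:5]}")
        bad = set(self.gene_types.unique()) - set(RNA_TYPES)
        if bad:
            raise ValidationError(f"unknown RNA type(s): {sorted(bad)}")
        arr = self.values.to_numpy(dtype=float)
        if not np.isfinite(arr).all():
            raise ValidationError("expression values must be finite")
        if not self.log_transformed and (arr < 0).any():
            raise ValidationError("RPKM-scale expression values must be >= 0")
        self.values = self.values.astype(float)

    # -- basic views ---------------------------------------------------

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    # -- derived matrices ----------------------------------------------

    def select_genes(self, gene_ids) -> "ExpressionMatrix":
        """Row subset in the given order (ids must exist)."""
        gene_ids = list(gene_ids)
        missing = [g for g in gene_ids if g not in self.values.index]
        if missing:
            raise ValidationError(f"unknown gene ids: {missing[:5]}")
        return ExpressionMatrix(
            self.values.loc[gene_ids].copy(),
            self.gene_types.loc[gene_ids].copy(),
            self.log_transformed,
        )

    def with_samples(self, sample_ids) -> "ExpressionMatrix":
        """Column subset / reordering."""
        return ExpressionMatrix(
            self.values.loc[:, list(sample_ids)].copy(),
            self.gene_types.copy(),
            self.log_transformed,
        )

    def copy(self) -> "ExpressionMatrix":
        return ExpressionMatrix(
            self.values.copy(), self.gene_types.copy(), self.log_transformed
        )

    def type_counts(self) -> dict[str, int]:
        """Number of genes per RNA type (all three keys always present)."""
        vc = self.gene_types.value_counts()
        return {t: int(vc.get(t, 0)) for t in RNA_TYPES}
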