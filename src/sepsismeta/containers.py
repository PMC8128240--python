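"""Core data container for merged microarray meta-expression data.

An :class:`ExpressionSet` couples a gene-by-sample matrix of (log2-scale)
expression intensities with a sample metadata table carrying the class label
(sepsis / healthy / SIRS / trauma, or the consolidated binary labels), the
originating study and the microarray platform.  It is the currency passed
between every pipeline stage: simulation, merging, batch adjustment,
differential expression, scaling and classification.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

VALID_CLASSES = ("sepsis", "healthy", "SIRS", "trauma")

#: metadata columns every ExpressionSet carries
META_COLUMNS = ("class", "study", "platform")


class ExpressionSetError(ValueError):
    """Raised when matrix and metadata are inconsistent."""


@dataclass
class ExpressionSet:
    """Gene-by-sample expression matrix with aligned sample metadata.

    Parameters
    ----------
    values : pandas.DataFrame
        Genes as rows (index = gene identifiers), samples as columns
        (columns = sample identifiers).  Real-valued, log2-intensity-like.
    metadata : pandas.DataFrame
        One row per sample, indexed by sample identifier, with columns
        ``class``, ``study`` and ``platform``.  Row order must match the
        column order of ``values``.
    """

    values: pd.DataFrame
    metadata: pd.DataFrame

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            dups = self.values.index[self.values.index.duplicated()].unique()
            raise ExpressionSetError(f"duplicate gene identifiers: {list(dups[:5])}")
        if self.values.columns.duplicated().any():
            dups = self.values.columns[self.values.columns.duplicated()].unique()
            raise ExpressionSetError(f"duplicate sample identifiers: {list(dups[:5])}")
        if len(self.metadata) != self.values.shape[1]:
            raise ExpressionSetError(
                f"metadata has {len(self.metadata)} rows but matrix has "
                f"{self.values.shape[1]} samples"
            )
        if not (self.metadata.index == self.values.columns).all():
            raise ExpressionSetError("metadata index does not align with matrix columns")
        missing = [c for c in META_COLUMNS if c not in self.metadata.columns]
        if missing:
            raise ExpressionSetError(f"metadata missing columns: {missing}")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    def subset_genes(self, genes) -> "ExpressionSet":
        """Restrict to the given genes (order follows `genes`)."""
        genes = pd.Index(genes)
        absent = genes.difference(self.gene_ids)
        if len(absent):
            raise ExpressionSetError(f"genes not present: {list(absent[:5])}")
        return ExpressionSet(self.values.loc[genes], self.metadata.copy())

    def drop_genes(self, genes) -> "ExpressionSet":
        """Remove the given genes, keeping the remaining gene order."""
        keep = self.gene_ids.difference(pd.Index(genes), sort=False)
        return ExpressionSet(self.values.loc[keep], self.metadata.copy())

    def subset_samples(self, sample_ids) -> "ExpressionSet":
        sample_ids = pd.Index(sample_ids)
        return ExpressionSet(
            self.values.loc[:, sample_ids], self.metadata.loc[sample_ids].copy()
        )

    def copy(self) -> "ExpressionSet":
        return ExpressionSet(self.values.copy(), self.metadata.copy())

    # ------------------------------------------------------------------ I/O
    def to_tsv(self, expression_path, metadata_path) -> None:
        """Write the genes-x-samples matrix and the metadata table as TSV.

        The expression file has a header row of sample IDs and the gene ID
        as first column; the metadata file has columns
        sample_id, class, study, platform.
        """
        self.values.to_csv(expression_path, sep="\t", index_label="gene_id")
        meta = self.metadata.reset_index(names="sample_id")
        meta.to_csv(metadata_path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, expression_path, metadata_path) -> "ExpressionSet":
        values = pd.read_csv(expression_path, sep="\t", index_col="gene_id")
        values.index.name = None  # in-memory sets carry an unnamed gene index
        meta = pd.read_csv(metadata_path, sep="\t").set_index("sample_id")
        return cls(values, meta)
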