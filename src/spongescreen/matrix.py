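"""Expression-matrix container shared by every pipeline stage.

The container is a thin, validated wrapper around a pandas DataFrame of
genes x samples values, plus per-gene class labels (lncRNA / miRNA / mRNA),
per-sample condition labels (tumor / normal) and an optional pairing label
for matched tumor/adjacent designs.  The value scale is tracked explicitly
(``counts`` or ``log2cpm``) so downstream stages can refuse the wrong one.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

GENE_CLASSES = ("lncRNA", "miRNA", "mRNA")
CONDITIONS = ("tumor", "normal")

_VERSION_SUFFIX = re.compile(r"\.\d+$")


def normalize_gene_id(gene_id: str) -> str:
    """Canonical gene id: Ensembl version suffix stripped, upper-cased.

    Mixed id dialects (versioned Ensembl ids vs bare symbols) are the most
    common practical cause of silently empty set intersections, so every
    set-level operation routes ids through here first.
    """
    return _VERSION_SUFFIX.sub("", str(gene_id).strip()).upper()


def infer_gene_class(gene_id: str) -> str | None:
    """Infer the gene class from the synthetic id prefix (LNC/MIR/MR)."""
    gid = gene_id.upper()
    if gid.startswith("LNC"):
        return "lncRNA"
    if gid.startswith("MIR") or gid.startswith("HSA-MIR"):
        return "miRNA"
    if gid.startswith("MR"):
        return "mRNA"
    return None


@dataclass
class ExpressionMatrix:
    """Genes x samples expression values with gene/sample annotations.

    Parameters
    ----------
    values
        DataFrame indexed by gene id with sample ids as columns.
    gene_class
        Series mapping gene id -> one of ``lncRNA``/``miRNA``/``mRNA``.
        If omitted, classes are inferred from id prefixes where possible.
    condition
        Series mapping sample id -> ``tumor`` or ``normal``.
    scale
        ``"counts"`` (non-negative) or ``"log2cpm"``.
    pair_id
        Optional Series mapping sample id -> pair label for matched designs.
    """

    values: pd.DataFrame
    condition: pd.Series
    gene_class: pd.Series | None = None
    scale: str = "counts"
    pair_id: pd.Series | None = field(default=None)

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            dup = self.values.index[self.values.index.duplicated()][0]
            raise ValueError(f"duplicate gene id: {dup!r}")
        if self.values.columns.duplicated().any():
            dup = self.values.columns[self.values.columns.duplicated()][0]
            raise ValueError(f"duplicate sample id: {dup!r}")
        if self.scale not in ("counts", "log2cpm"):
            raise ValueError(f"unknown scale: {self.scale!r}")
        if not np.issubdtype(np.asarray(self.values.values).dtype, np.number):
            raise ValueError("expression values must be numeric")
        if self.scale == "counts" and (self.values.values < 0).any():
            raise ValueError("counts must be non-negative")
        self.condition = self.condition.reindex(self.values.columns)
        if self.condition.isna().any():
            missing = self.condition.index[self.condition.isna()][0]
            raise ValueError(f"sample {missing!r} has no condition label")
        bad = set(self.condition.unique()) - set(CONDITIONS)
        if bad:
            raise ValueError(f"unknown condition label(s): {sorted(bad)}")
        if self.gene_class is None:
            inferred = {g: infer_gene_class(g) for g in self.values.index}
            self.gene_class = pd.Series(inferred, dtype=object)
        else:
            self.gene_class = self.gene_class.reindex(self.values.index)
        if self.pair_id is not None:
            self.pair_id = self.pair_id.reindex(self.values.columns)

    # -- convenience accessors -------------------------------------------

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

    def genes_of_class(self, gene_class: str) -> list[str]:
        if gene_class not in GENE_CLASSES:
            raise ValueError(f"unknown gene class: {gene_class!r}")
        mask = self.gene_class == gene_class
        return list(self.gene_class.index[mask])

    def samples_of_condition(self, condition: str) -> list[str]:
        if condition not in CONDITIONS:
            raise ValueError(f"unknown condition: {condition!r}")
        return list(self.condition.index[self.condition == condition])

    def subset_samples(self, sample_ids) -> "ExpressionMatrix":
        sample_ids = list(sample_ids)
        return ExpressionMatrix(
            values=self.values[sample_ids].copy(),
            condition=self.condition.loc[sample_ids].copy(),
            gene_class=self.gene_class.copy(),
            scale=self.scale,
            pair_id=None if self.pair_id is None else self.pair_id.loc[sample_ids].copy(),
        )

    def tumor_only(self) -> "ExpressionMatrix":
        return self.subset_samples(self.samples_of_condition("tumor"))

    def expression_of(self, gene_id: str) -> pd.Series:
        if gene_id not in self.values.index:
            raise KeyError(f"gene {gene_id!r} not in matrix")
        return self.values.loc[gene_id]

    def library_sizes(self) -> pd.Series:
        if self.scale != "counts":
            raise ValueError("library sizes are defined on the counts scale")
        return self.values.sum(axis=0)
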