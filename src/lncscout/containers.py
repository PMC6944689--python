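"""Core in-memory containers: expression matrices and gene annotation.

Expression values live in a genes x samples :class:`pandas.DataFrame`; every
sample carries a class label (PAM50-style subtype or NORMAL) and the matrix is
tagged with its unit (``counts``, ``fpkm`` or ``normalized``). Gene annotation
uses 0-based half-open coordinates internally; GTF input/output converts at the
boundary (see :mod:`lncscout.io`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

SAMPLE_CLASSES = ("BL", "HER2", "LA", "LB", "NL", "NORMAL")

VALID_UNITS = ("counts", "fpkm", "normalized")


@dataclass
class ExpressionMatrix:
    """Genes x samples expression values with per-sample class labels.

    Parameters
    ----------
    values : pandas.DataFrame
        Non-negative expression values, index = gene ids, columns = sample ids.
    sample_class : pandas.Series
        Class label per sample, indexed by sample id (same set as columns).
    unit : str
        One of ``counts``, ``fpkm``, ``normalized``.
    """

    values: pd.DataFrame
    sample_class: pd.Series
    unit: str = "counts"

    def __post_init__(self) -> None:
        self.values = pd.DataFrame(self.values)
        self.sample_class = pd.Series(self.sample_class)
        if self.unit not in VALID_UNITS:
            raise ValueError(f"unknown unit {self.unit!r}; expected one of {VALID_UNITS}")
        if not self.values.index.is_unique:
            dup = self.values.index[self.values.index.duplicated()][0]
            raise ValueError(f"duplicate gene id {dup!r}")
        if not self.values.columns.is_unique:
            dup = self.values.columns[self.values.columns.duplicated()][0]
            raise ValueError(f"duplicate sample id {dup!r}")
        if (self.values.to_numpy() < 0).any():
            raise ValueError("expression values must be non-negative")
        missing = set(self.values.columns) - set(self.sample_class.index)
        if missing:
            raise ValueError(f"samples without class label: {sorted(missing)[:5]}")
        # align label order to the columns
        self.sample_class = self.sample_class.reindex(self.values.columns)

    # -- convenience -------------------------------------------------------
    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    def samples_of_class(self, label: str) -> list[str]:
        return list(self.sample_class.index[self.sample_class == label])

    def subset_genes(self, gene_ids) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values.loc[list(gene_ids)], self.sample_class, self.unit)

    def subset_samples(self, sample_ids) -> "ExpressionMatrix":
        ids = list(sample_ids)
        return ExpressionMatrix(self.values[ids], self.sample_class.loc[ids], self.unit)

    def with_unit(self, values: pd.DataFrame, unit: str) -> "ExpressionMatrix":
        return ExpressionMatrix(values, self.sample_class, unit)


@dataclass
class GeneAnnotation:
    """Gene coordinate/biotype table; 0-based half-open ``start``/``end``.

    ``table`` columns: gene_id (index), gene_name, biotype, chrom, start, end,
    strand, length_bp.
    """

    table: pd.DataFrame = field(default_factory=pd.DataFrame)

    REQUIRED = ("biotype", "chrom", "start", "end", "strand", "length_bp")

    def __post_init__(self) -> None:
        t = self.table
        for col in self.REQUIRED:
            if col not in t.columns:
                raise ValueError(f"annotation missing column {col!r}")
        if not t.index.is_unique:
            dup = t.index[t.index.duplicated()][0]
            raise ValueError(f"duplicate gene id {dup!r} in annotation")
        if (t["start"] >= t["end"]).any():
            bad = t.index[t["start"] >= t["end"]][0]
            raise ValueError(f"gene {bad!r} has start >= end")
        if (t["length_bp"] < 1).any():
            bad = t.index[t["length_bp"] < 1][0]
            raise ValueError(f"gene {bad!r} has non-positive length")
        if not t["strand"].isin(["+", "-", "."]).all():
            raise ValueError("strand must be one of '+', '-', '.'")

    @property
    def gene_ids(self) -> pd.Index:
        return self.table.index

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self.table.index

    def __len__(self) -> int:
        return len(self.table)

    def lengths(self, gene_ids) -> pd.Series:
        return self.table["length_bp"].reindex(list(gene_ids))

    def of_biotype(self, biotypes) -> pd.Index:
        return self.table.index[self.table["biotype"].isin(set(biotypes))]
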