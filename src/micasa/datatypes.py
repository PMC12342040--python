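"""Core in-memory containers for the analysis pipeline.

The central object is :class:`AbundanceTable`, an ASV (or any taxon) by
sample matrix of non-negative integer counts backed by a pandas DataFrame.
A :class:`Dataset` bundles the table with its taxonomy, sample metadata and
an optional rooted phylogenetic tree for UniFrac.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from skbio import TreeNode

RANKS = ("domain", "phylum", "class", "order", "family", "genus", "species")
UNASSIGNED = "unassigned"


class ValidationError(ValueError):
    """Raised when a table, taxonomy or metadata object violates its contract."""


@dataclass
class AbundanceTable:
    """Taxon-by-sample count matrix with aligned, unique identifiers.

    Parameters
    ----------
    df : pandas.DataFrame
        Rows are taxa (ASVs, genera, ...), columns are samples. Values must
        be non-negative integers.
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.df
        if df.index.has_duplicates:
            dup = df.index[df.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate taxon IDs: {dup}")
        if df.columns.has_duplicates:
            dup = df.columns[df.columns.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate sample IDs: {dup}")
        values = df.to_numpy()
        if values.size and not np.issubdtype(values.dtype, np.number):
            raise ValidationError("counts must be numeric")
        if values.size:
            if np.any(values < 0):
                raise ValidationError("counts must be non-negative")
            if not np.allclose(values, np.round(values)):
                raise ValidationError("counts must be integral")
        self.df = df.astype(np.int64)

    @property
    def asv_ids(self) -> list[str]:
        return list(self.df.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.df.columns)

    @property
    def counts(self) -> np.ndarray:
        """Counts as an int array, taxa x samples."""
        return self.df.to_numpy()

    @property
    def shape(self) -> tuple[int, int]:
        return self.df.shape

    def sample_sums(self) -> pd.Series:
        return self.df.sum(axis=0)

    def subset_taxa(self, taxon_ids) -> "AbundanceTable":
        return AbundanceTable(self.df.loc[list(taxon_ids)])

    def subset_samples(self, sample_ids) -> "AbundanceTable":
        return AbundanceTable(self.df[list(sample_ids)])


@dataclass
class TaxonomyTable:
    """ASV -> seven-rank assignment; missing ranks hold ``"unassigned"``."""

    df: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [r for r in RANKS if r not in self.df.columns]
        if missing:
            raise ValidationError(f"taxonomy missing rank columns: {missing}")
        if self.df.index.has_duplicates:
            dup = self.df.index[self.df.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate ASV IDs in taxonomy: {dup}")
        df = self.df[list(RANKS)].astype(str)
        df = df.replace({"": UNASSIGNED, "nan": UNASSIGNED, "None": UNASSIGNED})
        self.df = df


@dataclass
class SampleMetadata:
    """Per-sample design and environmental covariates.

    Required columns: ``group``, ``temperature``, ``timepoint``,
    ``replicate``, ``phase``. Any additional numeric column is treated as an
    environmental covariate (pH, TS, VS, ammonium, ...).
    """

    df: pd.DataFrame

    REQUIRED = ("group", "temperature", "timepoint", "replicate", "phase")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.df.columns]
        if missing:
            raise ValidationError(f"metadata missing columns: {missing}")
        if self.df.index.has_duplicates:
            dup = self.df.index[self.df.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate sample IDs in metadata: {dup}")
        if self.df["temperature"].isna().any() or self.df["timepoint"].isna().any():
            raise ValidationError("temperature and timepoint must be defined for all samples")

    def covariate_columns(self) -> list[str]:
        extra = [c for c in self.df.columns if c not in ("group", "timepoint", "replicate", "phase")]
        return [c for c in extra if pd.api.types.is_numeric_dtype(self.df[c])]


@dataclass
class Dataset:
    """An abundance table with aligned taxonomy, metadata and optional tree."""

    table: AbundanceTable
    taxonomy: TaxonomyTable
    metadata: SampleMetadata
    tree: Optional[TreeNode] = field(default=None)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        table_samples = set(self.table.sample_ids)
        meta_samples = set(self.metadata.df.index)
        missing_meta = sorted(table_samples - meta_samples)
        if missing_meta:
            raise ValidationError(f"samples absent from metadata: {missing_meta}")
        missing_tax = sorted(set(self.table.asv_ids) - set(self.taxonomy.df.index))
        if missing_tax:
            raise ValidationError(f"ASVs absent from taxonomy: {missing_tax}")
        if self.tree is not None:
            leaves = {t.name for t in self.tree.tips()}
            missing_leaves = sorted(set(self.table.asv_ids) - leaves)
            if missing_leaves:
                raise ValidationError(f"ASVs absent from tree: {missing_leaves}")

    def filter_samples(self, mask: pd.Series) -> "Dataset":
        """Subset samples by a boolean mask aligned to the metadata index."""
        keep = [s for s in self.table.sample_ids if bool(mask.get(s, False))]
        return Dataset(
            table=self.table.subset_samples(keep),
            taxonomy=self.taxonomy,
            metadata=SampleMetadata(self.metadata.df.loc[keep]),
            tree=self.tree,
        )

    def filter_taxa(self, taxon_ids) -> "Dataset":
        keep = list(taxon_ids)
        return Dataset(
            table=self.table.subset_taxa(keep),
            taxonomy=TaxonomyTable(self.taxonomy.df.loc[keep]),
            metadata=self.metadata,
            tree=self.tree,
        )
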