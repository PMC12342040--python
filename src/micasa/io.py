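"""Reading, writing and preprocessing of abundance/taxonomy/metadata tables.

File dialects
-------------
* Abundance: TSV, first column ``feature_id``, remaining columns sample IDs,
  taxa as rows. A transposed table (samples as rows) is detected by header
  overlap with the metadata sample IDs and auto-transposed with a warning.
* Taxonomy: TSV with ``feature_id`` plus either seven rank columns or a
  single QIIME-style semicolon-delimited ``Taxon`` column.
* Metadata: TSV with ``sample_id`` first.
* Tree: newick with branch lengths.
"""

from __future__ import annotations

import logging
import warnings
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from skbio import TreeNode

from .datatypes import (
    RANKS,
    UNASSIGNED,
    AbundanceTable,
    Dataset,
    SampleMetadata,
    TaxonomyTable,
    ValidationError,
)

logger = logging.getLogger(__name__)


def _parse_qiime_taxon_strings(taxon: pd.Series) -> pd.DataFrame:
    """Split 'd__Bacteria; p__Proteobacteria; ...' strings into rank columns."""
    rows = []
    for value in taxon.fillna(""):
        parts = [p.strip() for p in str(value).split(";")]
        labels = []
        for part in parts:
            if "__" in part:
                part = part.split("__", 1)[1]
            labels.append(part if part else UNASSIGNED)
        labels = (labels + [UNASSIGNED] * len(RANKS))[: len(RANKS)]
        rows.append(labels)
    return pd.DataFrame(rows, index=taxon.index, columns=list(RANKS))


def read_taxonomy(path) -> TaxonomyTable:
    df = pd.read_csv(path, sep="\t", dtype=str)
    df = df.set_index(df.columns[0])
    df.index.name = None
    lower = {c.lower(): c for c in df.columns}
    if all(r in lower for r in RANKS):
        ranks = df[[lower[r] for r in RANKS]]
        ranks.columns = list(RANKS)
    elif "taxon" in lower:
        ranks = _parse_qiime_taxon_strings(df[lower["taxon"]])
    else:
        raise ValidationError(
            "taxonomy must provide the seven rank columns or a 'Taxon' column"
        )
    return TaxonomyTable(ranks)


def read_metadata(path) -> SampleMetadata:
    df = pd.read_csv(path, sep="\t")
    df = df.set_index(df.columns[0])
    df.index = df.index.astype(str)
    df.index.name = None
    return SampleMetadata(df)


def read_abundance(path, metadata: Optional[SampleMetadata] = None) -> AbundanceTable:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.index.name = None
    df.columns = df.columns.astype(str)
    if metadata is not None:
        samples = set(metadata.df.index)
        col_overlap = len(samples & set(df.columns))
        row_overlap = len(samples & set(df.index))
        if row_overlap > col_overlap:
            warnings.warn(
                "abundance table appears transposed (samples as rows); auto-transposing",
                stacklevel=2,
            )
            df = df.T
    values = df.to_numpy()
    if values.size and not np.issubdtype(values.dtype, np.number):
        bad = df.columns[[not np.issubdtype(d, np.number) for d in df.dtypes]].tolist()
        raise ValidationError(f"non-numeric counts in columns: {bad}")
    if values.size and not np.allclose(values, np.round(values)):
        raise ValidationError("non-integer counts in abundance table")
    return AbundanceTable(df)


def read_dataset(
    abundance_path,
    taxonomy_path,
    metadata_path,
    tree_path=None,
) -> Dataset:
    """Read and cross-validate the full input bundle.

    Raises
    ------
    FileNotFoundError
        If any path does not exist.
    ValidationError
        On duplicate IDs, non-integer counts, or ID mismatches between the
        table, metadata, taxonomy and tree (the offending IDs are named).
    """
    for p in (abundance_path, taxonomy_path, metadata_path, tree_path):
        if p is not None and not Path(p).exists():
            raise FileNotFoundError(p)
    metadata = read_metadata(metadata_path)
    table = read_abundance(abundance_path, metadata=metadata)
    taxonomy = read_taxonomy(taxonomy_path)
    tree = None
    if tree_path is not None:
        tree = TreeNode.read(str(tree_path), format="newick")
    # restrict metadata to the table's samples, preserving table order
    meta = SampleMetadata(
        metadata.df.loc[[s for s in table.sample_ids if s in metadata.df.index]]
    )
    return Dataset(table=table, taxonomy=taxonomy, metadata=meta, tree=tree)


def write_dataset(ds: Dataset, out_dir) -> dict[str, Path]:
    """Write the bundle back to TSV/newick; inverse of :func:`read_dataset`."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "abundance": out / "abundance.tsv",
        "taxonomy": out / "taxonomy.tsv",
        "metadata": out / "metadata.tsv",
    }
    ds.table.df.rename_axis("feature_id").to_csv(paths["abundance"], sep="\t")
    ds.taxonomy.df.rename_axis("feature_id").to_csv(paths["taxonomy"], sep="\t")
    ds.metadata.df.rename_axis("sample_id").to_csv(paths["metadata"], sep="\t")
    if ds.tree is not None:
        paths["tree"] = out / "tree.nwk"
        ds.tree.write(str(paths["tree"]), format="newick")
    return paths


def filter_contaminants_and_unassigned(ds: Dataset) -> Dataset:
    """Drop organellar contaminants and fully unassigned ASVs.

    Removes ASVs whose family or order matches "mitochondria", whose order
    matches "chloroplast" (case-insensitive substring), and ASVs whose every
    rank is the ``unassigned`` sentinel.
    """
    tax = ds.taxonomy.df.loc[ds.table.asv_ids]
    fam = tax["family"].str.lower()
    order = tax["order"].str.lower()
    is_mito = fam.str.contains("mitochondria") | order.str.contains("mitochondria")
    is_chloro = order.str.contains("chloroplast")
    is_unassigned = (tax.to_numpy() == UNASSIGNED).all(axis=1)
    is_unassigned = pd.Series(is_unassigned, index=tax.index)
    drop = is_mito | is_chloro | is_unassigned
    logger.info(
        "filtered ASVs: %d mitochondria, %d chloroplast, %d fully unassigned",
        int(is_mito.sum()),
        int((is_chloro & ~is_mito).sum()),
        int((is_unassigned & ~is_mito & ~is_chloro).sum()),
    )
    keep = tax.index[~drop]
    if len(keep) == 0:
        raise ValidationError("no ASVs remain after contaminant/unassigned filtering")
    if drop.sum() == 0:
        return ds
    return ds.filter_taxa(keep)


def aggregate_to_rank(ds: Dataset, rank: str) -> AbundanceTable:
    """Sum ASV counts into unique labels at a taxonomic rank.

    ASVs unassigned at that rank are pooled into ``Unassigned-<rank>``.
    Column sums are conserved exactly.
    """
    if rank not in RANKS:
        raise ValueError(f"unknown rank {rank!r}; expected one of {RANKS}")
    labels = ds.taxonomy.df.loc[ds.table.asv_ids, rank]
    labels = labels.where(labels != UNASSIGNED, f"Unassigned-{rank}")
    grouped = ds.table.df.groupby(labels.to_numpy()).sum()
    grouped.index.name = ds.table.df.index.name
    return AbundanceTable(grouped)


def relative_abundance(table: AbundanceTable) -> pd.DataFrame:
    """Close each sample column to proportions (columns sum to 1)."""
    sums = table.sample_sums()
    zero = sums.index[sums == 0].tolist()
    if zero:
        raise ValidationError(f"zero-sum samples: {zero}")
    return table.df / sums


def top_n_taxa(table: AbundanceTable, n: int) -> AbundanceTable:
    """Keep the ``n`` taxa with largest mean relative abundance.

    Ties break lexicographically by taxon ID; remaining taxa are dropped,
    not pooled.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if n > table.shape[0]:
        warnings.warn(
            f"requested top {n} taxa but table has only {table.shape[0]}; returning all",
            stacklevel=2,
        )
        n = table.shape[0]
    mean_rel = relative_abundance(table).mean(axis=1)
    order = sorted(mean_rel.index, key=lambda t: (-mean_rel[t], t))
    keep = order[:n]
    return table.subset_taxa(keep)
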