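import numpy as np
import pandas as pd
import pytest

from micasa import default_fixture
from micasa.datatypes import (
    RANKS,
    UNASSIGNED,
    AbundanceTable,
    Dataset,
    SampleMetadata,
    TaxonomyTable,
)


def make_taxonomy(asv_ids, genus=None, **overrides):
    rows = {}
    for i, a in enumerate(asv_ids):
        row = {r: f"{r}_{i}" for r in RANKS}
        if genus is not None:
            row["genus"] = genus[i]
        row.update({k: v[i] for k, v in overrides.items()})
        rows[a] = row
    return TaxonomyTable(pd.DataFrame.from_dict(rows, orient="index")[list(RANKS)])


def make_metadata(sample_ids, **overrides):
    n = len(sample_ids)
    base = {
        "group": ["Low"] * n,
        "temperature": [15.0] * n,
        "timepoint": [1] * n,
        "replicate": list(range(1, n + 1)),
        "phase": ["DNA-enrichment"] * n,
    }
    base.update(overrides)
    return SampleMetadata(pd.DataFrame(base, index=pd.Index(sample_ids, name="sample_id")))


def make_dataset(counts, asv_ids=None, sample_ids=None, taxonomy=None, metadata=None, tree=None):
    counts = np.asarray(counts)
    asv_ids = asv_ids or [f"ASV_{i}" for i in range(counts.shape[0])]
    if sample_ids is None:
        sample_ids = (
            list(metadata.df.index) if metadata is not None
            else [f"S{i}" for i in range(counts.shape[1])]
        )
    table = AbundanceTable(pd.DataFrame(counts, index=asv_ids, columns=sample_ids))
    return Dataset(
        table=table,
        taxonomy=taxonomy or make_taxonomy(asv_ids),
        metadata=metadata or make_metadata(sample_ids),
        tree=tree,
    )


@pytest.fixture(scope="session")
def fixture_seed0():
    """Default synthetic fixture (full design, planted structure), seed 0."""
    return default_fixture(seed=0)


@pytest.fixture(scope="session")
def dna_seed0(fixture_seed0):
    ds, truth = fixture_seed0
    return ds.filter_samples(ds.metadata.df["phase"] == "DNA-enrichment"), truth


@pytest.fixture
def tiny_dataset():
    """3 ASVs x 4 samples, 2 timepoints x 2 replicates."""
    counts = np.array([[5, 3, 4, 6], [0, 2, 1, 0], [10, 10, 9, 11]])
    meta = make_metadata(
        ["S0", "S1", "S2", "S3"],
        timepoint=[1, 1, 2, 2],
        replicate=[1, 2, 1, 2],
    )
    return make_dataset(counts, metadata=meta)
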