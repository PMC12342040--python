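"""Occupancy-ranked core-microbiome selection.

Taxa are ranked by a score combining time-specific occupancy with
replication consistency; the core is the ranking prefix whose cumulative
contribution to mean pairwise Bray–Curtis similarity keeps growing by more
than a relative threshold (the "last 2%" rule): each step's contribution is
``C = 1 - BC(subset) / BC(all)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datatypes import AbundanceTable, Dataset


def occupancy_profiles(ds: Dataset, group: str | None = None) -> pd.DataFrame:
    """Per-taxon occupancy profile on one group's samples.

    Returns a DataFrame indexed by taxon with columns:

    * ``mean_rel_abundance`` — mean within-sample relative abundance,
    * ``occ_t<i>`` — fraction of timepoint ``i``'s replicates with a count
      of at least one read,
    * ``occupancy`` — fraction of all samples occupied,
    * ``replication_consistency`` — fraction of timepoints where the taxon
      is detected in every replicate,
    * ``ranking_index`` — ``(mean_t occ_t + replication_consistency) / 2``.
    """
    meta = ds.metadata.df
    if group is not None:
        keep = meta.index[meta["group"] == group]
        if len(keep) == 0:
            raise ValueError(f"no samples in group {group!r}")
    else:
        keep = meta.index
    if len(keep) < 2:
        raise ValueError("occupancy profiles need at least two samples")
    sub = ds.table.df[list(keep)]
    meta = meta.loc[keep]
    present = (sub >= 1).to_numpy()
    rel = sub / sub.sum(axis=0)

    timepoints = sorted(meta["timepoint"].unique())
    occ_t = np.zeros((sub.shape[0], len(timepoints)))
    consistent = np.zeros((sub.shape[0], len(timepoints)), dtype=bool)
    for k, t in enumerate(timepoints):
        cols = (meta["timepoint"] == t).to_numpy()
        occ_t[:, k] = present[:, cols].mean(axis=1)
        consistent[:, k] = present[:, cols].all(axis=1)

    out = pd.DataFrame(index=sub.index)
    out["mean_rel_abundance"] = rel.mean(axis=1)
    for k, t in enumerate(timepoints):
        out[f"occ_t{t}"] = occ_t[:, k]
    out["occupancy"] = present.mean(axis=1)
    out["replication_consistency"] = consistent.mean(axis=1)
    out["ranking_index"] = (occ_t.mean(axis=1) + out["replication_consistency"]) / 2.0
    return out


def rank_taxa(profiles: pd.DataFrame) -> list[str]:
    """Ranking by descending index; ties by descending abundance, then ID."""
    idx = profiles["ranking_index"]
    ab = profiles["mean_rel_abundance"]
    return sorted(profiles.index, key=lambda t: (-idx[t], -ab[t], t))


def mean_bray_curtis_similarity(counts: np.ndarray) -> float:
    """Mean over sample pairs of 1 - Bray-Curtis dissimilarity (raw counts).

    A pair whose two subset totals are both zero is treated as identical
    (similarity 1); a pair with exactly one zero total is maximally
    dissimilar.
    """
    x = np.asarray(counts, dtype=float)  # taxa x samples
    n = x.shape[1]
    sums = x.sum(axis=0)
    sim = []
    for i in range(n):
        for j in range(i + 1, n):
            denom = sums[i] + sums[j]
            if denom == 0:
                sim.append(1.0)
            else:
                sim.append(2.0 * np.minimum(x[:, i], x[:, j]).sum() / denom)
    return float(np.mean(sim))


def explanatory_curve(table: AbundanceTable, ranking: list[str]) -> pd.DataFrame:
    """``E_k = BC(top-k subset) / BC(all)`` for every prefix of the ranking.

    The subset similarity of a sample pair is the shared (minimum) mass of
    the top-k taxa over the pair's *full* sample totals, i.e. the fraction
    of overall Bray–Curtis similarity those k taxa account for. This makes
    ``E_k`` monotone non-decreasing, 0 at an empty subset and exactly 1 at
    the full ranking — the S-shaped explanatory-value curve whose step gain
    feeds the last-2% rule. Returns a DataFrame with columns ``taxon``,
    ``E`` and ``C`` (= 1 - E) indexed by k = 1..K.
    """
    if len(ranking) == 0:
        raise ValueError("empty ranking")
    x = table.df.loc[ranking].to_numpy(dtype=float)
    n = x.shape[1]
    ii, jj = np.triu_indices(n, k=1)
    full_sums = table.counts.sum(axis=0).astype(float)
    if np.any(full_sums == 0):
        raise ValueError("zero-sum sample in explanatory-curve input")
    bc_all = mean_bray_curtis_similarity(table.counts)
    if bc_all == 0:
        raise ValueError("mean Bray-Curtis similarity of the full table is zero")
    denom = full_sums[ii] + full_sums[jj]
    shared = np.zeros(len(ii))
    e = np.empty(len(ranking))
    for k in range(len(ranking)):
        row = x[k]
        shared += np.minimum(row[ii], row[jj])
        e[k] = float((2.0 * shared / denom).mean()) / bc_all
    return pd.DataFrame(
        {"taxon": ranking, "E": e, "C": 1.0 - e},
        index=pd.RangeIndex(1, len(ranking) + 1, name="k"),
    )


def select_core(curve: pd.DataFrame, threshold: float = 0.02) -> tuple[list[str], int]:
    """Apply the last-2% rule to the explanatory-value curve.

    The stop index is the largest k whose relative gain
    ``(E_k - E_{k-1}) / E_{k-1}`` exceeds ``threshold``; the top-ranked
    taxon is always included. Returns ``(core_taxa, stop_index)``.
    """
    if len(curve) == 0:
        raise ValueError("empty explanatory curve")
    e = curve["E"].to_numpy()
    stop = 1
    for k in range(1, len(e)):
        prev = e[k - 1]
        gain = (e[k] - prev) / prev if prev > 0 else np.inf
        if gain > threshold:
            stop = k + 1
    return curve["taxon"].iloc[:stop].tolist(), stop


@dataclass
class CoreResult:
    group: str | None
    profiles: pd.DataFrame
    ranking: list[str]
    bc_all: float
    curve: pd.DataFrame
    core: list[str]
    stop_index: int
    threshold: float


def core_microbiome(
    ds: Dataset,
    group: str | None = None,
    threshold: float = 0.02,
    max_rank: int | None = None,
) -> CoreResult:
    """Full occupancy-ranking + explanatory-curve core selection.

    ``max_rank`` caps the curve length for very large tables; the stop
    criterion almost always fires within the first few dozen taxa.
    """
    profiles = occupancy_profiles(ds, group)
    ranking = rank_taxa(profiles)
    if group is not None:
        meta = ds.metadata.df
        table = ds.table.subset_samples(meta.index[meta["group"] == group])
    else:
        table = ds.table
    if max_rank is not None:
        ranking_used = ranking[:max_rank]
    else:
        ranking_used = ranking
    curve = explanatory_curve(table, ranking_used)
    core, stop = select_core(curve, threshold)
    return CoreResult(
        group=group,
        profiles=profiles,
        ranking=ranking,
        bc_all=mean_bray_curtis_similarity(table.counts),
        curve=curve,
        core=core,
        stop_index=stop,
        threshold=threshold,
    )
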