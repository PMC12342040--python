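"""Synthetic ASV-table generator with known community-assembly structure.

Emulates a temperature-gradient enrichment-reactor design: three temperature
groups (Low/Meso/Thermo) sampled at four timepoints in triplicate
(DNA-phase), plus a shorter cDNA-like phase, with uneven sequencing depth.
Taxa are assembled neutrally (Sloan model: local relative abundance drawn
from a Beta distribution parameterized by ``N*m`` and the source abundance),
optionally with planted non-neutral taxa (environmentally selected /
dispersal limited), a planted persistent core, and a temperature-like
covariate generated from a zero-sum log-contrast signal. Every dataset is
emitted with a :class:`SyntheticTruth` record so downstream modules can be
validated by parameter recovery.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from skbio import TreeNode

from .datatypes import RANKS, UNASSIGNED, AbundanceTable, Dataset, SampleMetadata, TaxonomyTable
from . import io as mio

GROUP_TEMPS = {"Low": 15.0, "Meso": 35.0, "Thermo": 48.0}
GROUP_PH = {"Low": 8.6, "Meso": 8.9, "Thermo": 9.1}


@dataclass
class SimulationConfig:
    """Generator settings; defaults mirror the emulated reactor design."""

    n_taxa: int = 300
    n_groups: int = 3
    timepoints_per_group: int = 4
    replicates_per_timepoint: int = 3
    depth_range: tuple[int, int] = (11_000, 124_000)
    local_community_size: Optional[int] = None  # None -> mean of depth_range
    m_true: float = 0.15
    source_alpha: float = 0.7
    n_planted_core: int = 0
    n_planted_above: int = 0
    n_planted_below: int = 0
    n_signal_taxa: int = 0
    beta_magnitude: float = 6.0
    signal_fold: float = 1.6  # per-group fold response of signal taxa
    noise_sd: float = 0.5
    cdna_timepoints: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.m_true <= 1):
            raise ValueError("m_true must lie in (0, 1]")
        if self.depth_range[0] > self.depth_range[1]:
            raise ValueError("depth_range min must be <= max")
        if min(self.n_taxa, self.n_groups, self.timepoints_per_group,
               self.replicates_per_timepoint) < 1:
            raise ValueError("design counts must be positive")
        n_planted = self.n_planted_core + self.n_planted_above + self.n_planted_below
        if n_planted + self.n_signal_taxa > self.n_taxa:
            raise ValueError("planted + signal taxa exceed n_taxa")

    @property
    def community_size(self) -> int:
        if self.local_community_size is not None:
            return self.local_community_size
        return int(round(sum(self.depth_range) / 2))


@dataclass
class SyntheticTruth:
    """Ground truth emitted with every simulated dataset."""

    source_p: dict[str, float]
    m_true: float
    planted_core_ids: list[str] = field(default_factory=list)
    planted_above_ids: list[str] = field(default_factory=list)
    planted_below_ids: list[str] = field(default_factory=list)
    signal_beta: dict[str, float] = field(default_factory=dict)
    signal_intercept: float = 0.0
    seed: int = 0

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=1)


def simulate_source_community(n_taxa: int, source_alpha: float, seed: int) -> np.ndarray:
    """Draw a long-tailed source (metacommunity) relative-abundance vector.

    A symmetric Dirichlet with concentration ``source_alpha`` < 1 yields the
    few-dominants / many-rare rank-abundance shape typical of 16S surveys.
    """
    if n_taxa < 2:
        raise ValueError("n_taxa must be >= 2")
    rng = np.random.default_rng(seed)
    p = rng.dirichlet(np.full(n_taxa, source_alpha))
    # guard against exact zeros from extreme draws
    p = np.maximum(p, 1e-12)
    return p / p.sum()


def _taxon_ids(n: int) -> list[str]:
    return [f"ASV_{i:04d}" for i in range(1, n + 1)]


def _synthetic_taxonomy(asv_ids: list[str]) -> TaxonomyTable:
    """One synthetic genus per ASV, nested in a handful of higher ranks."""
    phyla = ["Pseudomonadota", "Bacteroidota", "Actinomycetota", "Bacillota"]
    rows = {}
    for i, asv in enumerate(asv_ids):
        rows[asv] = {
            "domain": "Bacteria",
            "phylum": phyla[i % len(phyla)],
            "class": f"Class_{i % 8:02d}",
            "order": f"Order_{i % 16:02d}",
            "family": f"Family_{i % 32:02d}",
            "genus": f"Genus_{i + 1:04d}",
            "species": UNASSIGNED,
        }
    return TaxonomyTable(pd.DataFrame.from_dict(rows, orient="index")[list(RANKS)])


def simulate_tree(asv_ids: list[str], seed: int) -> TreeNode:
    """Random coalescent-style rooted binary tree over the taxa."""
    rng = np.random.default_rng(seed)
    nodes = [TreeNode(name=a, length=float(rng.exponential(0.1)) + 0.01) for a in asv_ids]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        right = nodes.pop(j)
        left = nodes.pop(i)
        parent = TreeNode(children=[left, right], length=float(rng.exponential(0.1)) + 0.01)
        nodes.append(parent)
    root = nodes[0]
    root.length = None
    return root


def _design(cfg: SimulationConfig) -> pd.DataFrame:
    """Sample sheet for the DNA-phase (and optional cDNA-like) design."""
    group_names = list(GROUP_TEMPS)[: cfg.n_groups]
    if cfg.n_groups > len(group_names):
        group_names += [f"Group{i}" for i in range(len(group_names) + 1, cfg.n_groups + 1)]
    rows = []
    for g in group_names:
        temp = GROUP_TEMPS.get(g, 20.0 + 10.0 * group_names.index(g))
        for t in range(1, cfg.timepoints_per_group + 1):
            for r in range(1, cfg.replicates_per_timepoint + 1):
                rows.append(
                    {
                        "sample_id": f"{g}_{t}_r{r}",
                        "group": g,
                        "temperature": temp,
                        "timepoint": t,
                        "replicate": r,
                        "phase": "DNA-enrichment",
                    }
                )
        for t in range(1, cfg.cdna_timepoints + 1):
            phase = "cDNA-accumulation" if t == cfg.cdna_timepoints else "cDNA-enrichment"
            prefix = "Acc" if t == cfg.cdna_timepoints else "Enr"
            for r in range(1, cfg.replicates_per_timepoint + 1):
                rows.append(
                    {
                        "sample_id": f"{prefix}_{g}_{t}_r{r}",
                        "group": g,
                        "temperature": temp,
                        "timepoint": t,
                        "replicate": r,
                        "phase": phase,
                    }
                )
    return pd.DataFrame(rows).set_index("sample_id")


def simulate_neutral_dataset(cfg: SimulationConfig) -> tuple[Dataset, SyntheticTruth]:
    """Generate a purely neutrally assembled dataset.

    For each sample, per-taxon local relative abundance is drawn from
    ``Beta(N*m*p_i, N*m*(1 - p_i))``, the draws are renormalized across taxa
    (an accepted approximation of joint neutral sampling), and counts are
    drawn multinomially at a depth uniform over ``depth_range``.
    """
    rng = np.random.default_rng(cfg.seed)
    asv_ids = _taxon_ids(cfg.n_taxa)
    p = simulate_source_community(cfg.n_taxa, cfg.source_alpha, cfg.seed)
    design = _design(cfg)
    N = cfg.community_size
    nm = N * cfg.m_true
    counts = np.zeros((cfg.n_taxa, len(design)), dtype=np.int64)
    for s in range(len(design)):
        local = rng.beta(nm * p, nm * (1.0 - p))
        local = local / local.sum()
        depth = int(rng.integers(cfg.depth_range[0], cfg.depth_range[1] + 1))
        counts[:, s] = rng.multinomial(depth, local)
    # environmental covariates: group-level values with small measurement noise
    meta = design.copy()
    ph_base = meta["group"].map(lambda g: GROUP_PH.get(g, 8.8)).astype(float)
    meta["pH"] = (ph_base + rng.normal(0, 0.05, len(meta))).round(3)
    meta["ammonium"] = (5.0 + 0.1 * (meta["temperature"] - 30.0)
                        + rng.normal(0, 0.5, len(meta))).round(3)
    meta["VS"] = (2.0 + rng.normal(0, 0.2, len(meta))).round(3)
    table = AbundanceTable(pd.DataFrame(counts, index=asv_ids, columns=design.index))
    ds = Dataset(
        table=table,
        taxonomy=_synthetic_taxonomy(asv_ids),
        metadata=SampleMetadata(meta),
        tree=simulate_tree(asv_ids, cfg.seed + 1),
    )
    truth = SyntheticTruth(
        source_p=dict(zip(asv_ids, p.tolist())),
        m_true=cfg.m_true,
        seed=cfg.seed,
    )
    return ds, truth


def plant_non_neutral_taxa(
    ds: Dataset, truth: SyntheticTruth, cfg: SimulationConfig
) -> tuple[Dataset, SyntheticTruth]:
    """Overwrite selected taxa with deterministic assembly patterns.

    * "above" taxa (environmentally selected): present (>= 1 read) in every
      sample at very low abundance, so observed occupancy sits far above the
      neutral expectation for their mean abundance.
    * "below" taxa (dispersal limited): abundant, but confined to a single
      replicate line, so occupancy sits far below the neutral expectation.
    * "core" taxa: dominant and present in every replicate at every
      timepoint of every group — the persistent enrichment core.
    """
    n_plant = cfg.n_planted_core + cfg.n_planted_above + cfg.n_planted_below
    if n_plant == 0:
        return ds, truth
    if n_plant > cfg.n_taxa:
        raise ValueError("requested planted counts exceed n_taxa")
    rng = np.random.default_rng(cfg.seed + 2)
    asv_ids = ds.table.asv_ids
    chosen = rng.choice(len(asv_ids), size=n_plant, replace=False)
    core_idx = chosen[: cfg.n_planted_core]
    above_idx = chosen[cfg.n_planted_core : cfg.n_planted_core + cfg.n_planted_above]
    below_idx = chosen[cfg.n_planted_core + cfg.n_planted_above :]

    counts = ds.table.counts.copy()
    depths = counts.sum(axis=0)
    replicate = ds.metadata.df["replicate"].to_numpy()
    # dominant persistent core: per-taxon share of each sample's reads,
    # well above the neutral tail (enrichment cores dominate the community)
    for k, i in enumerate(core_idx):
        share = rng.uniform(0.08, 0.12)
        jitter = rng.uniform(0.8, 1.2, size=len(depths))
        counts[i, :] = np.maximum(1, np.round(share * jitter * depths)).astype(np.int64)
    # ubiquitous but rare: a handful of reads everywhere
    for i in above_idx:
        counts[i, :] = 1 + rng.poisson(2.0, size=len(depths))
    # abundant but dispersal limited to replicate line 1
    for i in below_idx:
        share = rng.uniform(0.01, 0.03)
        in_line = replicate == 1
        counts[i, :] = 0
        counts[i, in_line] = np.maximum(
            1, np.round(share * rng.uniform(0.8, 1.2, in_line.sum()) * depths[in_line])
        ).astype(np.int64)

    table = AbundanceTable(pd.DataFrame(counts, index=asv_ids, columns=ds.table.sample_ids))
    ds2 = Dataset(table=table, taxonomy=ds.taxonomy, metadata=ds.metadata, tree=ds.tree)
    truth.planted_core_ids = [asv_ids[i] for i in core_idx]
    truth.planted_above_ids = [asv_ids[i] for i in above_idx]
    truth.planted_below_ids = [asv_ids[i] for i in below_idx]
    return ds2, truth


def simulate_covariate_response(
    ds: Dataset, truth: SyntheticTruth, cfg: SimulationConfig
) -> tuple[Dataset, SyntheticTruth]:
    """Generate a temperature-like covariate from a zero-sum log-contrast.

    Signal taxa first receive a group-dependent abundance response (their
    source abundance is scaled by ``signal_fold**(g * sign(beta_j))`` with
    ``g = -1, 0, +1`` across the ordered groups, and their counts are
    re-drawn) — temperature structures the community, as in the emulated
    reactors. The covariate is then read back off the realized table:
    ``y = b0 + sum_j beta_j * log(closed proportions with pseudocount 1) +
    Gaussian noise``, with coefficients nonzero only on the signal taxa,
    alternating in sign with magnitude ``beta_magnitude``; for an odd
    number of signal taxa the negative coefficients are rescaled so the
    vector still sums to zero exactly. The result overwrites the
    ``temperature`` metadata column and is recorded in the truth.
    """
    if cfg.n_signal_taxa == 0:
        return ds, truth
    rng = np.random.default_rng(cfg.seed + 3)
    asv_ids = ds.table.asv_ids
    planted = set(truth.planted_core_ids) | set(truth.planted_above_ids) | set(
        truth.planted_below_ids
    )
    # pick signal taxa among the most abundant unplanted taxa so they stay
    # inside downstream top-N subcompositions
    mean_rel = mio.relative_abundance(ds.table).mean(axis=1)
    candidates = [a for a in sorted(asv_ids, key=lambda a: -mean_rel[a]) if a not in planted]
    signal = candidates[: cfg.n_signal_taxa]
    signs = np.array([1.0 if k % 2 == 0 else -1.0 for k in range(len(signal))])
    beta = signs * cfg.beta_magnitude
    n_pos = int((signs > 0).sum())
    n_neg = int((signs < 0).sum())
    if n_neg and n_pos != n_neg:
        beta[signs < 0] *= n_pos / n_neg
    assert abs(beta.sum()) < 1e-9

    counts = ds.table.df.copy()
    if cfg.beta_magnitude > 0:
        groups = ds.metadata.df["group"]
        levels = list(dict.fromkeys(groups))
        gcode = groups.map({g: i - (len(levels) - 1) / 2 for i, g in enumerate(levels)})
        depths = counts.sum(axis=0)
        N = cfg.community_size
        nm = N * cfg.m_true
        source_p = np.array([truth.source_p[a] for a in signal])
        for j, taxon in enumerate(signal):
            fold = cfg.signal_fold ** (gcode.to_numpy() * signs[j])
            p_resp = np.minimum(source_p[j] * fold, 0.5)
            local = rng.beta(nm * p_resp, nm * (1.0 - p_resp))
            counts.loc[taxon] = rng.binomial(depths.to_numpy(), local)

    pseudo = counts + 1
    logx = np.log(pseudo / pseudo.sum(axis=0))
    b0 = 30.0
    y = b0 + logx.loc[signal].T.to_numpy() @ beta + rng.normal(0, cfg.noise_sd, counts.shape[1])
    meta = ds.metadata.df.copy()
    meta["temperature"] = np.round(y, 6)
    table = AbundanceTable(counts)
    ds2 = Dataset(
        table=table, taxonomy=ds.taxonomy, metadata=SampleMetadata(meta), tree=ds.tree
    )
    truth.signal_beta = dict(zip(signal, beta.tolist()))
    truth.signal_intercept = b0
    return ds2, truth


def simulate_dataset(cfg: SimulationConfig) -> tuple[Dataset, SyntheticTruth]:
    """Full generator: neutral backbone, planted taxa, covariate signal."""
    ds, truth = simulate_neutral_dataset(cfg)
    ds, truth = plant_non_neutral_taxa(ds, truth, cfg)
    ds, truth = simulate_covariate_response(ds, truth, cfg)
    return ds, truth


def default_fixture(seed: int = 0) -> tuple[Dataset, SyntheticTruth]:
    """The standard test fixture: full design with all planted structure."""
    cfg = SimulationConfig(
        n_planted_core=10,
        n_planted_above=5,
        n_planted_below=5,
        n_signal_taxa=5,
        cdna_timepoints=3,
        seed=seed,
    )
    return simulate_dataset(cfg)


def write_fixture(ds: Dataset, truth: SyntheticTruth, out_dir) -> dict[str, Path]:
    """Write TSV/newick fixture files plus the ground-truth JSON."""
    paths = mio.write_dataset(ds, out_dir)
    truth_path = Path(out_dir) / "truth.json"
    truth_path.write_text(truth.to_json())
    paths["truth"] = truth_path
    return paths
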