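"""Full-analysis orchestration: preprocess -> diversity -> core -> neutral
-> CODA-LASSO, with deterministic, seed-stamped TSV/JSON outputs."""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import pandas as pd

from . import __version__, codalasso, core, diversity, io as mio
from .datatypes import Dataset

logger = logging.getLogger(__name__)

DNA_PHASES = ("DNA-enrichment",)
CDNA_PHASES = ("cDNA-enrichment", "cDNA-accumulation")


@dataclass
class RunConfig:
    abundance: Optional[str] = None
    taxonomy: Optional[str] = None
    metadata: Optional[str] = None
    tree: Optional[str] = None
    out_dir: str = "micasa_out"
    group_column: str = "group"
    rarefaction_depth: Optional[int] = None
    permutations: int = 999
    seed: int = 0
    core_threshold: float = 0.02
    core_max_rank: Optional[int] = 200
    ci_level: float = 0.95
    coda_top: int = 100
    coda_folds: int = 5
    coda_covariate: str = "temperature"

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


@dataclass
class AnalysisReport:
    alpha: pd.DataFrame
    permanova_table: pd.DataFrame
    core_results: dict[str, core.CoreResult] = field(default_factory=dict)
    neutral_fits: dict = field(default_factory=dict)
    coda_fit: Optional[codalasso.CodaLassoFit] = None
    provenance: dict = field(default_factory=dict)

    def write(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        fmt = lambda df: df.map(  # noqa: E731 - 10 sig digits keeps outputs regression-stable
            lambda v: float(f"{v:.10g}") if isinstance(v, float) else v
        )
        fmt(self.alpha).rename_axis("sample_id").to_csv(out / "alpha_diversity.tsv", sep="\t")
        fmt(self.permanova_table).to_csv(out / "permanova.tsv", sep="\t", index=False)
        for group, res in self.core_results.items():
            fmt(res.profiles).rename_axis("taxon").to_csv(
                out / f"core_occupancy_{group}.tsv", sep="\t"
            )
            fmt(res.curve).to_csv(out / f"core_curve_{group}.tsv", sep="\t")
            (out / f"core_members_{group}.txt").write_text("\n".join(res.core) + "\n")
        for group, fit in self.neutral_fits.items():
            fmt(fit.per_taxon).rename_axis("taxon").to_csv(
                out / f"neutral_{group}.tsv", sep="\t"
            )
            (out / f"neutral_{group}.json").write_text(
                json.dumps(
                    {"m": fit.m, "N": fit.N, "d": fit.d, "R2": fit.r_squared,
                     "n_samples": fit.n_samples, "reliable": fit.reliable},
                    indent=1,
                )
            )
        if self.coda_fit is not None:
            coef = pd.DataFrame(
                {
                    "beta": self.coda_fit.beta,
                    "sign_set": [
                        "positive" if b > 0 else ("negative" if b < 0 else "zero")
                        for b in self.coda_fit.beta
                    ],
                }
            )
            fmt(coef).rename_axis("taxon").to_csv(out / "codalasso_coefficients.tsv", sep="\t")
            if self.coda_fit.cv_curve is not None:
                fmt(self.coda_fit.cv_curve).to_csv(
                    out / "codalasso_cv.tsv", sep="\t", index=False
                )
        (out / "provenance.json").write_text(json.dumps(self.provenance, indent=1))


def _permanova_rows(ds: Dataset, covariates: list[str], cfg: RunConfig) -> pd.DataFrame:
    metrics = {"bray_curtis": diversity.bray_curtis_matrix(ds.table)}
    if ds.tree is not None:
        metrics["unweighted_unifrac"] = diversity.unweighted_unifrac(ds.table, ds.tree)
        metrics["weighted_unifrac"] = diversity.weighted_unifrac(ds.table, ds.tree)
    rows = []
    for metric, dm in metrics.items():
        for cov in covariates:
            t0 = time.perf_counter()
            res = diversity.permanova(
                dm, ds.metadata.df[cov], n_permutations=cfg.permutations,
                seed=cfg.seed, name=cov,
            )
            logger.info("PERMANOVA %s/%s: %.2fs", metric, cov, time.perf_counter() - t0)
            row = res.as_dict()
            row["metric"] = metric
            rows.append(row)
    return pd.DataFrame(rows)[
        ["metric", "covariate", "pseudo_F", "R2", "p", "n_permutations", "seed"]
    ]


def _load(cfg: RunConfig) -> Dataset:
    ds = mio.read_dataset(cfg.abundance, cfg.taxonomy, cfg.metadata, cfg.tree)
    return mio.filter_contaminants_and_unassigned(ds)


def run_enrichment_analysis(cfg: RunConfig, ds: Dataset | None = None) -> AnalysisReport:
    """DNA-phase analysis: alpha, PERMANOVA, per-group core + neutral, CODA."""
    if ds is None:
        ds = _load(cfg)
    phase = ds.metadata.df["phase"]
    dna = ds.filter_samples(phase.isin(DNA_PHASES))
    if dna.table.shape[1] == 0:
        raise ValueError("no DNA-phase samples found")
    covs = [cfg.group_column] + dna.metadata.covariate_columns()
    report = AnalysisReport(
        alpha=diversity.alpha_summary(dna.table, cfg.rarefaction_depth),
        permanova_table=_permanova_rows(dna, covs, cfg),
        provenance={
            "stage": "enrichment",
            "config": asdict(cfg),
            "config_hash": cfg.config_hash(),
            "version": __version__,
            "seed": cfg.seed,
        },
    )
    from .neutral import fit_neutral_model

    for group in sorted(dna.metadata.df[cfg.group_column].unique()):
        gds = dna.filter_samples(dna.metadata.df[cfg.group_column] == group)
        report.core_results[group] = core.core_microbiome(
            gds, threshold=cfg.core_threshold, max_rank=cfg.core_max_rank
        )
        report.neutral_fits[group] = fit_neutral_model(
            gds.table, ci_level=cfg.ci_level, group=group
        )
    report.coda_fit = codalasso.temperature_signature(
        dna, covariate=cfg.coda_covariate, n_top=cfg.coda_top,
        n_folds=cfg.coda_folds, seed=cfg.seed,
    )
    return report


def run_phase_comparison(cfg: RunConfig, ds: Dataset | None = None) -> AnalysisReport:
    """cDNA-phase analysis: alpha + PERMANOVA with the phase covariate."""
    if ds is None:
        ds = _load(cfg)
    phase = ds.metadata.df["phase"]
    if phase.nunique() < 2:
        raise ValueError("phase comparison needs at least two phases")
    cdna = ds.filter_samples(phase.isin(CDNA_PHASES))
    if cdna.table.shape[1] == 0:
        raise ValueError("no cDNA-phase samples found")
    covs = ["phase", cfg.group_column] + cdna.metadata.covariate_columns()
    return AnalysisReport(
        alpha=diversity.alpha_summary(cdna.table, cfg.rarefaction_depth),
        permanova_table=_permanova_rows(cdna, covs, cfg),
        provenance={
            "stage": "phase_comparison",
            "config": asdict(cfg),
            "config_hash": cfg.config_hash(),
            "version": __version__,
            "seed": cfg.seed,
        },
    )
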