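"""Sloan neutral community model: fit, prediction, and taxon classification.

The model predicts a taxon's occupancy (fraction of local communities in
which it is detected) from its mean relative abundance ``p`` in the source
community. Local relative abundance follows ``Beta(N*m*p, N*m*(1-p))``
where ``N`` is the local community size and ``m`` the migration
(immigration) rate — the single fitted parameter. Occupancy is the
probability that local abundance exceeds the detection limit ``d/N``:
``1 - I_{d/N}(N m p, N m (1 - p))`` with ``I`` the regularized incomplete
beta function. Taxa above the 95% band are read as environmentally
selected, taxa below as dispersal limited.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.special import betainc
from scipy.stats import norm

from .datatypes import AbundanceTable

M_BOUNDS = (1e-6, 1.0)


def predicted_occupancy(p, N: float, m: float, d: float = 1.0):
    """Probability that local relative abundance exceeds ``d / N``."""
    scalar = np.isscalar(p) or np.ndim(p) == 0
    p = np.atleast_1d(np.asarray(p, dtype=float))
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p must lie in [0, 1]")
    if N <= 0 or not (0 < m <= 1) or d < 1:
        raise ValueError("require N > 0, m in (0, 1], d >= 1")
    a = N * m * p
    b = N * m * (1.0 - p)
    out = np.zeros_like(p)
    inner = (p > 0) & (p < 1)
    out[inner] = 1.0 - betainc(a[inner], b[inner], d / N)
    out[p >= 1] = 1.0 if N > d else 0.0
    return float(out[0]) if scalar else out


def wilson_interval(prop, trials: int, ci_level: float = 0.95):
    """Wilson score interval for a binomial proportion (vectorized)."""
    if trials < 2:
        raise ValueError("need at least 2 trials")
    prop = np.asarray(prop, dtype=float)
    z = norm.ppf(0.5 + ci_level / 2.0)
    denom = 1.0 + z**2 / trials
    center = (prop + z**2 / (2 * trials)) / denom
    half = z * np.sqrt(prop * (1 - prop) / trials + z**2 / (4 * trials**2)) / denom
    return np.clip(center - half, 0, 1), np.clip(center + half, 0, 1)


@dataclass
class NeutralFit:
    m: float
    N: float
    d: float
    r_squared: float
    n_samples: int
    per_taxon: pd.DataFrame  # p, occupancy, predicted, ci_lower, ci_upper, class
    ci_level: float = 0.95
    reliable: bool = True
    group: str | None = None

    @property
    def class_counts(self) -> pd.Series:
        return self.per_taxon["class"].value_counts()


def fit_migration_parameter(
    p,
    occupancy,
    N: float,
    d: float = 1.0,
    min_taxa: int = 20,
) -> tuple[float, float, bool]:
    """Least-squares fit of ``m`` to an abundance-occupancy cloud.

    Returns ``(m_hat, r_squared, reliable)``. The fit is flagged unreliable
    when all observed occupancies are identical (no slope information).
    """
    p = np.asarray(p, dtype=float)
    occ = np.asarray(occupancy, dtype=float)
    mask = p > 0
    if mask.sum() < min_taxa:
        raise ValueError(f"need >= {min_taxa} taxa with p > 0, got {int(mask.sum())}")
    p, occ = p[mask], occ[mask]

    def sse(m: float) -> float:
        return float(np.sum((occ - predicted_occupancy(p, N, m, d)) ** 2))

    res = minimize_scalar(sse, bounds=M_BOUNDS, method="bounded",
                          options={"xatol": 1e-8})
    m_hat = float(res.x)
    sst = float(np.sum((occ - occ.mean()) ** 2))
    reliable = sst > 0
    r2 = 1.0 - res.fun / sst if sst > 0 else np.nan
    return m_hat, r2, reliable


def classify_taxa(per_taxon: pd.DataFrame, n_samples: int, ci_level: float = 0.95) -> pd.DataFrame:
    """Label taxa neutral / above / below a Wilson band around the prediction.

    The band treats the predicted occupancy as a binomial proportion
    observed over ``n_samples`` trials.
    """
    lower, upper = wilson_interval(per_taxon["predicted"].to_numpy(), n_samples, ci_level)
    out = per_taxon.copy()
    out["ci_lower"] = lower
    out["ci_upper"] = upper
    out["class"] = "neutral"
    out.loc[out["occupancy"] > out["ci_upper"], "class"] = "above"
    out.loc[out["occupancy"] < out["ci_lower"], "class"] = "below"
    return out


def fit_neutral_model(
    table: AbundanceTable,
    N: float | None = None,
    d: float = 1.0,
    ci_level: float = 0.95,
    detection_threshold: int = 1,
    group: str | None = None,
) -> NeutralFit:
    """Fit the neutral model to a table's abundance-occupancy distribution.

    ``p`` is each taxon's mean within-sample relative abundance, occupancy
    the fraction of samples with at least ``detection_threshold`` reads.
    ``N`` defaults to the mean sample depth.
    """
    counts = table.counts
    n_samples = counts.shape[1]
    if n_samples < 2:
        raise ValueError("need at least 2 samples")
    depths = counts.sum(axis=0)
    if N is None:
        N = float(depths.mean())
    rel = counts / depths
    p = rel.mean(axis=1)
    occ = (counts >= detection_threshold).mean(axis=1)
    m_hat, r2, reliable = fit_migration_parameter(p, occ, N, d)
    per_taxon = pd.DataFrame(
        {
            "p": p,
            "occupancy": occ,
            "predicted": predicted_occupancy(p, N, m_hat, d),
        },
        index=table.asv_ids,
    )
    per_taxon = classify_taxa(per_taxon, n_samples, ci_level)
    return NeutralFit(
        m=m_hat,
        N=N,
        d=d,
        r_squared=r2,
        n_samples=n_samples,
        per_taxon=per_taxon,
        ci_level=ci_level,
        reliable=reliable,
        group=group,
    )


def genus_class_tally(fit: NeutralFit, taxonomy: pd.DataFrame) -> pd.DataFrame:
    """Count neutral/above/below ASVs per genus (bar-plot style summary)."""
    genus = taxonomy.loc[fit.per_taxon.index, "genus"]
    tally = (
        fit.per_taxon.assign(genus=genus)
        .groupby(["genus", "class"])
        .size()
        .unstack(fill_value=0)
    )
    for col in ("neutral", "above", "below"):
        if col not in tally.columns:
            tally[col] = 0
    return tally[["neutral", "above", "below"]]
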