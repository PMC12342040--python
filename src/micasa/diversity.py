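"""Alpha diversity, beta-diversity distance matrices, ordination, PERMANOVA.

Distances are returned as :class:`skbio.DistanceMatrix`. PERMANOVA follows
the McArdle–Anderson linear-model formulation on the Gower-centered matrix,
which handles categorical factors and numeric covariates (distance-matrix
regression) in one frame; factors are tested one at a time (marginal R²).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln, xlogy
from skbio import DistanceMatrix, TreeNode
from skbio.diversity import beta_diversity

from .datatypes import AbundanceTable


# ---------------------------------------------------------------- alpha

def expected_rarefied_richness(counts, depth: int) -> float:
    """Expected number of taxa in a random subsample of ``depth`` reads.

    Hypergeometric expectation: ``E[S] = sum_i 1 - C(N - N_i, n) / C(N, n)``
    evaluated with log-gamma for numerical stability at large ``N``.
    """
    counts = np.asarray(counts)
    counts = counts[counts > 0]
    total = int(counts.sum())
    if depth > total:
        raise ValueError(f"rarefaction depth {depth} exceeds sample total {total}")
    if depth == total:
        return float(len(counts))

    def log_comb(n, k):
        return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)

    rest = total - counts
    miss = np.where(
        rest >= depth,
        np.exp(log_comb(rest, depth) - log_comb(total, depth)),
        0.0,
    )
    return float(np.sum(1.0 - miss))


def rarefied_richness_montecarlo(counts, depth: int, n_draws: int, seed: int) -> tuple[float, float]:
    """Monte-Carlo subsampling estimate of rarefied richness (mean, SE)."""
    rng = np.random.default_rng(seed)
    counts = np.asarray(counts, dtype=np.int64)
    pool = np.repeat(np.arange(len(counts)), counts)
    richness = np.empty(n_draws)
    for d in range(n_draws):
        sub = rng.choice(pool, size=depth, replace=False)
        richness[d] = len(np.unique(sub))
    return float(richness.mean()), float(richness.std(ddof=1) / np.sqrt(n_draws))


def shannon_entropy(counts) -> float:
    """Shannon entropy in nats, ``H = -sum p_i ln p_i`` over positive taxa."""
    counts = np.asarray(counts, dtype=float)
    total = counts.sum()
    if total <= 0:
        raise ValueError("all-zero sample")
    p = counts / total
    return float(-np.sum(xlogy(p, p)))


def alpha_summary(table: AbundanceTable, rarefaction_depth: int | None = None) -> pd.DataFrame:
    """Per-sample rarefied richness and Shannon entropy.

    Default rarefaction depth is the minimum sample depth.
    """
    sums = table.sample_sums()
    depth = int(sums.min()) if rarefaction_depth is None else rarefaction_depth
    rows = {}
    for s in table.sample_ids:
        c = table.df[s].to_numpy()
        rows[s] = {
            "rarefied_richness": expected_rarefied_richness(c, min(depth, int(c.sum()))),
            "shannon": shannon_entropy(c),
            "depth": int(c.sum()),
        }
    return pd.DataFrame.from_dict(rows, orient="index")


# ---------------------------------------------------------------- beta

def bray_curtis_matrix(table: AbundanceTable) -> DistanceMatrix:
    """Pairwise Bray–Curtis dissimilarity on raw counts."""
    x = table.counts.T.astype(float)  # samples x taxa
    sums = x.sum(axis=1)
    if np.any(sums == 0):
        raise ValueError("zero-sum sample in Bray-Curtis input")
    n = x.shape[0]
    d = np.zeros((n, n))
    for i in range(n):
        shared = np.minimum(x[i], x[i + 1 :]).sum(axis=1)
        d[i, i + 1 :] = 1.0 - 2.0 * shared / (sums[i] + sums[i + 1 :])
    d = d + d.T
    return DistanceMatrix(d, ids=table.sample_ids)


def _validate_tree_coverage(table: AbundanceTable, tree: TreeNode) -> None:
    # coverage and branch-length checks are done here; multifurcating
    # (e.g. star) trees are accepted, so skbio's own validation is skipped
    for node in tree.traverse(include_self=False):
        if node.length is None:
            raise ValueError("tree has branches without lengths")
    leaves = {t.name for t in tree.tips()}
    present = set(np.asarray(table.asv_ids)[(table.counts > 0).any(axis=1)])
    missing = sorted(present - leaves)
    if missing:
        raise ValueError(f"taxa with nonzero counts absent from tree: {missing}")


def unweighted_unifrac(table: AbundanceTable, tree: TreeNode) -> DistanceMatrix:
    """Unweighted UniFrac: unique / total branch length over presence sets."""
    _validate_tree_coverage(table, tree)
    return beta_diversity(
        "unweighted_unifrac",
        table.counts.T,
        ids=table.sample_ids,
        taxa=table.asv_ids,
        tree=tree,
        validate=False,
    )


def weighted_unifrac(table: AbundanceTable, tree: TreeNode, normalized: bool = True) -> DistanceMatrix:
    """Weighted UniFrac on per-sample relative abundances."""
    _validate_tree_coverage(table, tree)
    return beta_diversity(
        "weighted_unifrac",
        table.counts.T,
        ids=table.sample_ids,
        taxa=table.asv_ids,
        tree=tree,
        normalized=normalized,
        validate=False,
    )


# ---------------------------------------------------------------- ordination

@dataclass
class PcoaResult:
    coordinates: pd.DataFrame  # samples x axes
    eigenvalues: np.ndarray  # all eigenvalues, descending (negatives reported)
    proportion_explained: np.ndarray  # over positive eigenvalues only


def pcoa(dm: DistanceMatrix, n_axes: int | None = None) -> PcoaResult:
    """Classical scaling (principal coordinate analysis).

    Double-centers ``-D**2 / 2``, eigendecomposes, and scales eigenvectors by
    the square root of their (positive) eigenvalues. Negative eigenvalues are
    reported but excluded from coordinates and from the
    ``proportion_explained`` denominator.
    """
    d = dm.data
    n = d.shape[0]
    if n_axes is None:
        n_axes = n
    if n_axes > n:
        raise ValueError("n_axes exceeds number of samples")
    a = -0.5 * d**2
    j = np.eye(n) - np.ones((n, n)) / n
    g = j @ a @ j
    eigvals, eigvecs = np.linalg.eigh((g + g.T) / 2)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    pos = np.clip(eigvals, 0, None)
    coords = eigvecs * np.sqrt(pos)
    pos_sum = pos.sum()
    prop = pos / pos_sum if pos_sum > 0 else np.zeros(n)
    axes = [f"PC{i + 1}" for i in range(n_axes)]
    return PcoaResult(
        coordinates=pd.DataFrame(coords[:, :n_axes], index=list(dm.ids), columns=axes),
        eigenvalues=eigvals,
        proportion_explained=prop[:n_axes],
    )


# ---------------------------------------------------------------- permanova

@dataclass
class PermanovaResult:
    covariate: str
    pseudo_f: float
    r_squared: float
    p_value: float
    n_permutations: int
    seed: int

    def as_dict(self) -> dict:
        return {
            "covariate": self.covariate,
            "pseudo_F": self.pseudo_f,
            "R2": self.r_squared,
            "p": self.p_value,
            "n_permutations": self.n_permutations,
            "seed": self.seed,
        }


def _gower_center(d: np.ndarray) -> np.ndarray:
    n = d.shape[0]
    a = -0.5 * d**2
    j = np.eye(n) - np.ones((n, n)) / n
    return j @ a @ j


def _design_matrix(values: pd.Series) -> np.ndarray:
    """Full-rank design (with intercept) for one factor or numeric covariate."""
    if pd.api.types.is_numeric_dtype(values):
        x = values.to_numpy(dtype=float)
        return np.column_stack([np.ones(len(x)), x - x.mean()])
    levels = pd.unique(values)
    if len(levels) < 2:
        raise ValueError("categorical factor needs >= 2 levels")
    counts = values.value_counts()
    if (counts < 2).any():
        small = counts.index[counts < 2].tolist()
        raise ValueError(f"groups of size < 2: {small}")
    dummies = np.column_stack(
        [(values == lv).to_numpy(dtype=float) for lv in levels[:-1]]
    )
    return np.column_stack([np.ones(len(values)), dummies])


def permanova(
    dm: DistanceMatrix,
    covariate: pd.Series,
    n_permutations: int = 999,
    seed: int = 0,
    name: str | None = None,
    exhaustive: bool = False,
) -> PermanovaResult:
    """One-factor PERMANOVA (pseudo-F by permutation).

    With ``exhaustive=True`` every permutation of the samples is enumerated
    (small n only) and the exact permutation p-value is returned.

    ``SS_total = tr(G)`` with ``G`` the Gower-centered squared-distance
    matrix; ``SS_model = tr(H G)`` for the hat matrix ``H`` of the factor's
    design. For a categorical factor this equals the classical
    within/between-group pair decomposition; a numeric covariate gives
    distance-matrix regression. ``p = (1 + #{F_perm >= F_obs}) /
    (1 + n_permutations)`` under seeded sample permutations.
    """
    if n_permutations < 99:
        raise ValueError("n_permutations must be >= 99")
    ids = list(dm.ids)
    values = covariate.loc[ids]
    x = _design_matrix(values)
    n, k = x.shape
    df_model = k - 1
    df_resid = n - k
    if df_resid <= 0:
        raise ValueError("no residual degrees of freedom")
    g = _gower_center(dm.data)
    h = x @ np.linalg.pinv(x.T @ x) @ x.T
    ss_total = float(np.trace(g))
    rng = np.random.default_rng(seed)

    def pseudo_f(gmat: np.ndarray) -> tuple[float, float]:
        ss_model = float(np.sum(h * gmat))  # tr(H G), both symmetric
        ss_resid = float(np.trace(gmat)) - ss_model
        if ss_resid <= 0:
            return np.inf, ss_model
        return (ss_model / df_model) / (ss_resid / df_resid), ss_model

    f_obs, ss_model = pseudo_f(g)
    exceed = 0
    if exhaustive:
        from itertools import permutations as iter_perms

        count = 0
        for idx in iter_perms(range(n)):
            count += 1
            f_perm, _ = pseudo_f(g[np.ix_(np.array(idx), np.array(idx))])
            if f_perm >= f_obs - 1e-12:
                exceed += 1
        return PermanovaResult(
            covariate=name if name is not None else str(covariate.name),
            pseudo_f=f_obs,
            r_squared=ss_model / ss_total if ss_total > 0 else 0.0,
            p_value=exceed / count,
            n_permutations=count,
            seed=seed,
        )
    for _ in range(n_permutations):
        idx = rng.permutation(n)
        f_perm, _ = pseudo_f(g[np.ix_(idx, idx)])
        if f_perm >= f_obs - 1e-12:
            exceed += 1
    return PermanovaResult(
        covariate=name if name is not None else str(covariate.name),
        pseudo_f=f_obs,
        r_squared=ss_model / ss_total if ss_total > 0 else 0.0,
        p_value=(1 + exceed) / (1 + n_permutations),
        n_permutations=n_permutations,
        seed=seed,
    )
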