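"""Zero-sum-constrained L1 log-contrast regression (CODA-LASSO).

Models a numeric covariate ``y`` (temperature in the motivating design) as
``y_i = b0 + sum_j beta_j log x_ji + e_i`` with the compositional
constraint ``sum_j beta_j = 0``, which makes the fit invariant to the scale
of each sample's counts. The L1 penalty selects two disjoint signature
sets: taxa positively and negatively associated with the covariate.

The solver is pairwise coordinate descent: each update moves an amount
``delta`` from one coefficient to another, so the zero-sum constraint holds
exactly at every step. Each pair subproblem is a one-dimensional piecewise
quadratic solved in closed form.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import AbundanceTable, Dataset
from . import io as mio

try:  # JIT sweep kernel; the pure-Python path is the reference implementation
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def deco(f):
            return f

        return deco if not (args and callable(args[0])) else args[0]


def zero_replace_and_log(table: AbundanceTable) -> pd.DataFrame:
    """Pseudocount-1, close each sample to proportions, natural log.

    Returns a samples x taxa DataFrame of finite log proportions.
    """
    pseudo = table.df + 1
    closed = pseudo / pseudo.sum(axis=0)
    return np.log(closed).T


@dataclass
class CodaLassoFit:
    beta0: float
    beta: pd.Series
    lam: float
    objective: float
    n_iter: int
    converged: bool
    selected_positive: list[str] = field(default_factory=list)
    selected_negative: list[str] = field(default_factory=list)
    cv_curve: pd.DataFrame | None = None
    n_folds: int | None = None
    seed: int | None = None

    def predict(self, logx: pd.DataFrame) -> np.ndarray:
        return self.beta0 + logx[self.beta.index].to_numpy() @ self.beta.to_numpy()


def _pair_delta(a: float, b: float, bj: float, bk: float, lam: float) -> float:
    """Minimize ``0.5*a*d^2 - b*d + lam*(|bj + d| + |bk - d|)`` over ``d``.

    Piecewise quadratic with kinks at ``-bj`` and ``bk``; the minimum over
    each sign regime is clipped to its interval and the best candidate wins.
    """
    k0, k1 = sorted((-bj, bk))
    candidates = [k0, k1]
    # sign regimes: below both kinks, between, above both
    for lo, hi, probe in ((-np.inf, k0, k0 - 1.0), (k0, k1, (k0 + k1) / 2.0),
                          (k1, np.inf, k1 + 1.0)):
        s1 = 1.0 if bj + probe >= 0 else -1.0
        s2 = 1.0 if bk - probe >= 0 else -1.0
        d_star = (b - lam * (s1 - s2)) / a
        candidates.append(float(min(max(d_star, lo), hi)))

    def f(d: float) -> float:
        return 0.5 * a * d * d - b * d + lam * (abs(bj + d) + abs(bk - d))

    return min(candidates, key=f)


@njit
def _cd_sweeps(gram, zty, yty, beta, c, lam, tol, max_iter):  # pragma: no cover
    """Numba sweep kernel; mirrors :func:`_pair_delta` pair subproblems."""
    p = gram.shape[0]
    obj_prev = 1e300
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        for j in range(p - 1):
            for k in range(j + 1, p):
                a = gram[j, j] + gram[k, k] - 2.0 * gram[j, k]
                if a <= 1e-12:
                    continue
                b_lin = c[j] - c[k]
                bj = beta[j]
                bk = beta[k]
                k0 = -bj if -bj < bk else bk
                k1 = bk if -bj < bk else -bj
                best_d = k0
                best_f = 0.5 * a * k0 * k0 - b_lin * k0 + lam * (abs(bj + k0) + abs(bk - k0))
                f1 = 0.5 * a * k1 * k1 - b_lin * k1 + lam * (abs(bj + k1) + abs(bk - k1))
                if f1 < best_f:
                    best_f = f1
                    best_d = k1
                for regime in range(3):
                    if regime == 0:
                        lo, hi, probe = -1e308, k0, k0 - 1.0
                    elif regime == 1:
                        lo, hi, probe = k0, k1, 0.5 * (k0 + k1)
                    else:
                        lo, hi, probe = k1, 1e308, k1 + 1.0
                    s1 = 1.0 if bj + probe >= 0 else -1.0
                    s2 = 1.0 if bk - probe >= 0 else -1.0
                    d_star = (b_lin - lam * (s1 - s2)) / a
                    if d_star < lo:
                        d_star = lo
                    elif d_star > hi:
                        d_star = hi
                    fd = 0.5 * a * d_star * d_star - b_lin * d_star + lam * (
                        abs(bj + d_star) + abs(bk - d_star)
                    )
                    if fd < best_f:
                        best_f = fd
                        best_d = d_star
                if best_d != 0.0:
                    beta[j] += best_d
                    beta[k] -= best_d
                    for t in range(p):
                        c[t] -= best_d * (gram[t, j] - gram[t, k])
        # objective = 0.5 * ||r||^2 + lam * ||beta||_1 via the Gram identity
        quad = yty
        l1 = 0.0
        for j in range(p):
            quad -= 2.0 * beta[j] * zty[j]
            l1 += abs(beta[j])
            for k in range(p):
                quad += beta[j] * gram[j, k] * beta[k]
        obj = 0.5 * quad + lam * l1
        if obj_prev - obj < tol:
            converged = True
            break
        obj_prev = obj
    return it, converged


def fit_coda_lasso(
    logx: pd.DataFrame,
    y,
    lam: float,
    tol: float = 1e-8,
    max_iter: int = 2000,
    beta_init: np.ndarray | None = None,
) -> CodaLassoFit:
    """Solve the zero-sum lasso at one penalty weight.

    Minimizes ``0.5 * sum_i (y_i - b0 - sum_j beta_j z_ij)^2 +
    lam * sum_j |beta_j|`` subject to ``sum_j beta_j = 0``. Sweeps all
    coefficient pairs until the objective decrease falls below ``tol``.
    """
    if lam < 0:
        raise ValueError("lam must be >= 0")
    z = logx.to_numpy(dtype=float)
    y = np.asarray(y, dtype=float)
    if not (np.all(np.isfinite(z)) and np.all(np.isfinite(y))):
        raise ValueError("non-finite inputs")
    n, p = z.shape
    col_means = z.mean(axis=0)
    zc = z - col_means
    ybar = y.mean()
    yc = y - ybar
    gram = zc.T @ zc
    zty = zc.T @ yc
    beta = np.zeros(p) if beta_init is None else beta_init.copy()
    c = zty - gram @ beta  # gradient correlations Z'(r)
    diag = np.diag(gram)

    def objective(b: np.ndarray) -> float:
        r = yc - zc @ b
        return 0.5 * float(r @ r) + lam * float(np.abs(b).sum())

    if HAVE_NUMBA:
        yty = float(yc @ yc)
        it, converged = _cd_sweeps(
            np.ascontiguousarray(gram), zty, yty, beta, c, lam, tol, max_iter
        )
    else:
        obj = objective(beta)
        converged = False
        it = 0
        for it in range(1, max_iter + 1):
            for j in range(p - 1):
                gj = gram[:, j]
                for k in range(j + 1, p):
                    a = diag[j] + diag[k] - 2.0 * gram[j, k]
                    if a <= 1e-12:
                        continue
                    b_lin = c[j] - c[k]
                    d = _pair_delta(a, b_lin, beta[j], beta[k], lam)
                    if d != 0.0:
                        beta[j] += d
                        beta[k] -= d
                        c -= d * (gj - gram[:, k])
            new_obj = objective(beta)
            if obj - new_obj < tol:
                converged = True
                break
            obj = new_obj
    beta[np.abs(beta) < 1e-10] = 0.0
    # repair any accumulated drift in the constraint
    nz = beta != 0
    if nz.any():
        beta[nz] -= beta.sum() / nz.sum()
    beta0 = float(ybar - col_means @ beta)
    series = pd.Series(beta, index=logx.columns, name="beta")
    return CodaLassoFit(
        beta0=beta0,
        beta=series,
        lam=lam,
        objective=objective(beta),
        n_iter=it,
        converged=converged,
        selected_positive=series.index[series > 0].tolist(),
        selected_negative=series.index[series < 0].tolist(),
    )


def lambda_grid(logx: pd.DataFrame, y, n_lambda: int = 20, ratio: float = 1e-2) -> np.ndarray:
    """Log-spaced penalty grid from the all-zero threshold downward.

    The zero vector is optimal iff ``|c_j - c_k| <= 2*lam`` for every pair,
    so ``lam_max = (max_j c_j - min_j c_j) / 2`` with ``c = Z'y`` (centered).
    The floor ratio 1e-2 follows the usual lasso-path convention for the
    n < p regime.
    """
    z = logx.to_numpy(dtype=float)
    zc = z - z.mean(axis=0)
    yc = np.asarray(y, dtype=float) - np.mean(y)
    c = zc.T @ yc
    lam_max = float(c.max() - c.min()) / 2.0
    if lam_max <= 0:
        lam_max = 1.0
    return np.geomspace(lam_max, lam_max * ratio, n_lambda)


def cross_validate_lambda(
    logx: pd.DataFrame,
    y,
    grid=None,
    n_folds: int = 5,
    seed: int = 0,
) -> tuple[float, pd.DataFrame]:
    """Pick the penalty by k-fold CV mean squared error; ties -> larger lam.

    Folds are a seeded shuffle split; within each fold the penalty path is
    solved warm-started from large to small lambda.
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    if n_folds < 2:
        raise ValueError("n_folds must be >= 2")
    if grid is None:
        grid = lambda_grid(logx, y)
    grid = np.sort(np.asarray(grid, dtype=float))[::-1]
    if grid.size == 0:
        raise ValueError("empty lambda grid")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    folds = np.array_split(order, n_folds)
    if min(len(f) for f in folds) < 2:
        raise ValueError("a fold has fewer than 2 samples")
    errors = np.zeros((len(grid), n_folds))
    for f, test_idx in enumerate(folds):
        train_mask = np.ones(n, dtype=bool)
        train_mask[test_idx] = False
        lx_train = logx.iloc[train_mask]
        lx_test = logx.iloc[~train_mask]
        y_train, y_test = y[train_mask], y[~train_mask]
        warm = None
        for g, lam in enumerate(grid):
            fit = fit_coda_lasso(lx_train, y_train, lam, beta_init=warm)
            warm = fit.beta.to_numpy()
            resid = y_test - fit.predict(lx_test)
            errors[g, f] = float(np.mean(resid**2))
    mean_err = errors.mean(axis=1)
    best = int(np.argmin(mean_err))  # grid descends, argmin keeps largest lam on ties
    curve = pd.DataFrame({"lambda": grid, "cv_mse": mean_err})
    return float(grid[best]), curve


def temperature_signature(
    ds: Dataset,
    covariate: str = "temperature",
    n_top: int = 100,
    rank: str = "genus",
    n_folds: int = 5,
    seed: int = 0,
    grid=None,
) -> CodaLassoFit:
    """End-to-end covariate signature on the top-N most abundant taxa.

    Aggregates to ``rank``, keeps the ``n_top`` most abundant labels, runs
    pseudocount/closure/log, selects the penalty by CV and refits on the
    full data. Signatures come back sorted by decreasing |beta|.
    """
    if covariate not in ds.metadata.df.columns:
        raise ValueError(f"covariate {covariate!r} absent from metadata")
    y = ds.metadata.df.loc[ds.table.sample_ids, covariate].to_numpy(dtype=float)
    if np.any(~np.isfinite(y)):
        raise ValueError(f"covariate {covariate!r} missing for some samples")
    agg = mio.aggregate_to_rank(ds, rank)
    agg = mio.top_n_taxa(agg, min(n_top, agg.shape[0]))
    if agg.shape[0] < 2:
        raise ValueError("fewer than 2 taxa after aggregation/filtering")
    logx = zero_replace_and_log(agg)
    if np.ptp(y) == 0:
        # constant covariate: nothing to explain, empty signature
        beta = pd.Series(np.zeros(logx.shape[1]), index=logx.columns, name="beta")
        return CodaLassoFit(
            beta0=float(y.mean()), beta=beta, lam=np.inf, objective=0.0,
            n_iter=0, converged=True, n_folds=n_folds, seed=seed,
        )
    lam_star, curve = cross_validate_lambda(logx, y, grid=grid, n_folds=n_folds, seed=seed)
    fit = fit_coda_lasso(logx, y, lam_star)
    order = fit.beta.abs().sort_values(ascending=False).index
    fit.beta = fit.beta[order]
    fit.cv_curve = curve
    fit.n_folds = n_folds
    fit.seed = seed
    fit.selected_positive = [t for t in order if fit.beta[t] > 0]
    fit.selected_negative = [t for t in order if fit.beta[t] < 0]
    return fit
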