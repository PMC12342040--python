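import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize

from micasa import SimulationConfig, simulate_dataset
from micasa.codalasso import (
    cross_validate_lambda,
    fit_coda_lasso,
    lambda_grid,
    temperature_signature,
    zero_replace_and_log,
)
from micasa.datatypes import AbundanceTable

from conftest import make_dataset


def slsqp_oracle(z, y, lam):
    """Generic constrained QP solution via split positive/negative parts."""
    n, p = z.shape
    zc = z - z.mean(axis=0)
    yc = y - y.mean()

    def obj(v):
        b = v[:p] - v[p:]
        r = yc - zc @ b
        return 0.5 * r @ r + lam * v.sum()

    res = minimize(
        obj,
        np.zeros(2 * p),
        bounds=[(0, None)] * (2 * p),
        constraints=[{"type": "eq", "fun": lambda v: np.sum(v[:p] - v[p:])}],
        method="SLSQP",
        options={"maxiter": 1000, "ftol": 1e-14},
    )
    return res.fun


def random_problem(rng, n=20, p=10, signal=False):
    z = rng.normal(size=(n, p))
    if signal:
        y = 2.0 * (z[:, 0] - z[:, 1]) + rng.normal(scale=0.3, size=n)
    else:
        y = rng.normal(size=n)
    cols = [f"t{j:02d}" for j in range(p)]
    return pd.DataFrame(z, columns=cols), y


class TestZeroReplaceAndLog:
    def test_hand_pseudocount_value(self):
        ds = make_dataset(np.array([[0], [4], [5]]))
        logx = zero_replace_and_log(ds.table)
        assert logx.iloc[0, 0] == pytest.approx(np.log(1 / 12), abs=1e-12)

    def test_proportional_samples_identical_columns(self):
        ds = make_dataset(np.array([[1000, 10_000], [3000, 30_000]]))
        logx = zero_replace_and_log(ds.table)
        # closure removes scale up to the pseudocount's small distortion
        assert np.allclose(logx.iloc[0], logx.iloc[1], atol=1e-3)

    def test_no_negative_infinity(self):
        ds = make_dataset(np.zeros((3, 2), dtype=int) + np.eye(3, 2, dtype=int))
        assert np.isfinite(zero_replace_and_log(ds.table).to_numpy()).all()


class TestFitCodaLasso:
    def test_large_lambda_shrinks_everything(self):
        rng = np.random.default_rng(0)
        lx, y = random_problem(rng)
        fit = fit_coda_lasso(lx, y, lam=1e6)
        assert (fit.beta == 0).all()
        assert fit.beta0 == pytest.approx(np.mean(y), abs=1e-10)

    def test_two_taxon_signal_support_and_signs(self):
        rng = np.random.default_rng(1)
        lx, y = random_problem(rng, signal=True)
        fit = fit_coda_lasso(lx, y, lam=0.5)
        assert fit.beta["t00"] > 0 and fit.beta["t01"] < 0
        assert fit.beta.abs().nlargest(2).index.tolist() == ["t00", "t01"]

    def test_zero_sum_constraint_random_problems(self):
        rng = np.random.default_rng(2)
        for _ in range(10):
            lx, y = random_problem(rng, n=15, p=8)
            fit = fit_coda_lasso(lx, y, lam=rng.uniform(0.1, 5))
            assert abs(fit.beta.sum()) < 1e-8

    def test_objective_matches_constrained_qp_oracle(self):
        rng = np.random.default_rng(3)
        for rep in range(20):
            lx, y = random_problem(rng, n=20, p=10, signal=rep % 2 == 0)
            lam = float(rng.uniform(0.2, 3.0))
            fit = fit_coda_lasso(lx, y, lam)
            oracle = slsqp_oracle(lx.to_numpy(), y, lam)
            assert fit.objective <= oracle + 1e-6

    def test_python_reference_path_agrees_with_kernel(self, monkeypatch):
        import micasa.codalasso as cl

        rng = np.random.default_rng(4)
        lx, y = random_problem(rng, n=15, p=6, signal=True)
        fast = cl.fit_coda_lasso(lx, y, 0.4)
        monkeypatch.setattr(cl, "HAVE_NUMBA", False)
        slow = cl.fit_coda_lasso(lx, y, 0.4)
        assert slow.objective == pytest.approx(fast.objective, abs=1e-7)
        assert np.allclose(slow.beta, fast.beta, atol=1e-4)

    def test_scale_invariance_of_fit(self):
        cfg = SimulationConfig(n_taxa=60, n_signal_taxa=4, seed=5,
                               depth_range=(20_000, 40_000))
        ds, _ = simulate_dataset(cfg)
        y = ds.metadata.df["temperature"].to_numpy()
        base = fit_coda_lasso(zero_replace_and_log(ds.table), y, lam=2.0)
        scaled_counts = ds.table.df * 10
        scaled = fit_coda_lasso(
            zero_replace_and_log(AbundanceTable(scaled_counts)), y, lam=2.0
        )
        denom = np.abs(base.beta.to_numpy()).max()
        rel_change = np.abs(base.beta.to_numpy() - scaled.beta.to_numpy()).max() / denom
        assert rel_change < 0.01

    def test_nonfinite_inputs_rejected(self):
        lx = pd.DataFrame([[1.0, np.nan], [0.0, 1.0]], columns=["a", "b"])
        with pytest.raises(ValueError, match="non-finite"):
            fit_coda_lasso(lx, np.array([1.0, 2.0]), 0.1)


class TestCrossValidation:
    def test_determinism(self):
        rng = np.random.default_rng(6)
        lx, y = random_problem(rng, n=24, p=8, signal=True)
        lam1, curve1 = cross_validate_lambda(lx, y, n_folds=4, seed=3)
        lam2, curve2 = cross_validate_lambda(lx, y, n_folds=4, seed=3)
        assert lam1 == lam2
        pd.testing.assert_frame_equal(curve1, curve2)

    def test_single_value_grid_returned(self):
        rng = np.random.default_rng(7)
        lx, y = random_problem(rng, n=20, p=6)
        lam, _ = cross_validate_lambda(lx, y, grid=[0.7], n_folds=4, seed=0)
        assert lam == 0.7

    def test_pure_noise_prefers_null_model(self):
        """With no signal the CV-chosen penalty usually selects nothing and
        never builds a large model (min-CV lasso overselects mildly, so the
        null rate sits near two-thirds rather than one)."""
        rng = np.random.default_rng(8)
        supports = []
        n_rep = 25
        for rep in range(n_rep):
            lx, y = random_problem(rng, n=30, p=10)
            lam, _ = cross_validate_lambda(lx, y, n_folds=5, seed=rep)
            fit = fit_coda_lasso(lx, y, lam)
            supports.append(int((fit.beta != 0).sum()))
        supports = np.array(supports)
        assert (supports == 0).mean() >= 0.5
        assert np.median(supports) == 0

    def test_lambda_max_gives_empty_model(self):
        rng = np.random.default_rng(9)
        lx, y = random_problem(rng, n=20, p=8, signal=True)
        grid = lambda_grid(lx, y)
        fit = fit_coda_lasso(lx, y, float(grid[0]))
        assert (fit.beta == 0).all()


class TestTemperatureSignature:
    def test_planted_signal_recovered(self, dna_seed0):
        ds, truth = dna_seed0
        fit = temperature_signature(ds, seed=0)
        genus = ds.taxonomy.df["genus"]
        true_sign = {genus[a]: np.sign(b) for a, b in truth.signal_beta.items()}
        selected = {t: np.sign(b) for t, b in fit.beta.items() if b != 0}
        correct = sum(1 for g, s in true_sign.items() if selected.get(g, 0) == s)
        false_pos = len([t for t in selected if t not in true_sign])
        assert correct >= 4
        assert false_pos <= 5

    def test_signatures_disjoint_and_nonzero(self, dna_seed0):
        ds, _ = dna_seed0
        fit = temperature_signature(ds, seed=0)
        assert set(fit.selected_positive) & set(fit.selected_negative) == set()
        assert all(fit.beta[t] != 0 for t in fit.selected_positive + fit.selected_negative)
        assert abs(fit.beta.sum()) < 1e-8

    def test_constant_covariate_empty_signature(self, dna_seed0):
        ds, _ = dna_seed0
        meta = ds.metadata.df.copy()
        meta["temperature"] = 35.0
        from micasa.datatypes import Dataset, SampleMetadata

        flat = Dataset(ds.table, ds.taxonomy, SampleMetadata(meta), ds.tree)
        fit = temperature_signature(flat, seed=0)
        assert fit.selected_positive == [] and fit.selected_negative == []

    def test_missing_covariate_rejected(self, dna_seed0):
        ds, _ = dna_seed0
        with pytest.raises(ValueError, match="absent"):
            temperature_signature(ds, covariate="nope")
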