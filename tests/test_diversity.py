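import io

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix, TreeNode
from skbio.stats.distance import permanova as skbio_permanova

from micasa.datatypes import AbundanceTable
from micasa.diversity import (
    bray_curtis_matrix,
    expected_rarefied_richness,
    pcoa,
    permanova,
    rarefied_richness_montecarlo,
    shannon_entropy,
    unweighted_unifrac,
    weighted_unifrac,
)

from conftest import make_dataset


def table_from(counts, taxa=None, samples=None):
    counts = np.asarray(counts)
    taxa = taxa or [f"t{i}" for i in range(counts.shape[0])]
    samples = samples or [f"s{i}" for i in range(counts.shape[1])]
    return AbundanceTable(pd.DataFrame(counts, index=taxa, columns=samples))


def star_tree(taxa):
    return TreeNode.read(io.StringIO("(" + ",".join(f"{t}:1.0" for t in taxa) + ");"))


class TestAlpha:
    def test_rarefied_full_depth_is_observed_richness(self):
        assert expected_rarefied_richness([5, 0, 3, 2], 10) == 3

    def test_hand_case_two_equal_taxa(self):
        # counts (5,5), subsample 2: 2 * (1 - C(5,2)/C(10,2)) = 14/9
        assert expected_rarefied_richness([5, 5], 2) == pytest.approx(14 / 9, abs=1e-12)

    def test_single_taxon(self):
        assert expected_rarefied_richness([42], 5) == pytest.approx(1.0)

    def test_depth_exceeding_total_rejected(self):
        with pytest.raises(ValueError):
            expected_rarefied_richness([3, 3], 10)

    def test_matches_montecarlo_oracle(self):
        rng = np.random.default_rng(0)
        for rep in range(5):
            counts = rng.integers(0, 40, size=12)
            counts[0] += 1
            depth = int(counts.sum() // 3) + 1
            exact = expected_rarefied_richness(counts, depth)
            mc, se = rarefied_richness_montecarlo(counts, depth, 3000, seed=rep)
            assert abs(exact - mc) <= 3 * max(se, 1e-9)

    def test_large_counts_numerically_stable(self):
        counts = np.full(500, 10_000)
        val = expected_rarefied_richness(counts, 1000)
        assert 0 < val <= 500 and np.isfinite(val)

    def test_shannon_values(self):
        assert shannon_entropy([1, 1, 1, 1]) == pytest.approx(np.log(4), abs=1e-12)
        assert shannon_entropy([7]) == 0.0
        expected = -(0.25 * np.log(0.25) * 2 + 0.5 * np.log(0.5))
        assert shannon_entropy([1, 1, 2]) == pytest.approx(expected, abs=1e-12)
        with pytest.raises(ValueError):
            shannon_entropy([0, 0])


class TestBrayCurtis:
    def test_hand_example(self):
        tbl = table_from(np.array([[6, 2], [0, 4], [2, 2]]))
        assert bray_curtis_matrix(tbl)["s0", "s1"] == pytest.approx(0.5, abs=1e-12)

    def test_identical_and_disjoint(self):
        tbl = table_from(np.array([[3, 3, 0], [2, 2, 0], [0, 0, 5]]))
        dm = bray_curtis_matrix(tbl)
        assert dm["s0", "s1"] == 0.0
        assert dm["s0", "s2"] == 1.0

    def test_matches_scipy(self):
        rng = np.random.default_rng(1)
        counts = rng.integers(0, 50, size=(20, 8))
        counts[0] += 1  # no zero-sum column
        ours = bray_curtis_matrix(table_from(counts)).data
        ref = squareform(pdist(counts.T, metric="braycurtis"))
        assert np.allclose(ours, ref, atol=1e-12)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_distance_matrix_invariants(self, seed):
        rng = np.random.default_rng(seed)
        counts = rng.integers(0, 30, size=(6, 5))
        counts[rng.integers(0, 6)] += 1
        dm = bray_curtis_matrix(table_from(counts))
        assert np.allclose(np.diag(dm.data), 0)
        assert np.allclose(dm.data, dm.data.T, atol=1e-12)
        assert (dm.data >= 0).all() and (dm.data <= 1).all()


class TestUniFrac:
    def test_unweighted_star_equals_jaccard(self):
        rng = np.random.default_rng(2)
        counts = rng.integers(0, 10, size=(6, 5))
        counts[:, 0] += 1
        taxa = [f"t{i}" for i in range(6)]
        tbl = table_from(counts, taxa=taxa)
        dm = unweighted_unifrac(tbl, star_tree(taxa))
        pres = counts > 0
        for i in range(5):
            for j in range(i + 1, 5):
                inter = (pres[:, i] & pres[:, j]).sum()
                union = (pres[:, i] | pres[:, j]).sum()
                assert dm[f"s{i}", f"s{j}"] == pytest.approx(1 - inter / union, abs=1e-12)

    def test_weighted_star_equals_half_l1(self):
        rng = np.random.default_rng(3)
        counts = rng.integers(0, 25, size=(7, 4))
        counts[0] += 1
        taxa = [f"t{i}" for i in range(7)]
        tbl = table_from(counts, taxa=taxa)
        dm = weighted_unifrac(tbl, star_tree(taxa), normalized=True)
        rel = counts / counts.sum(axis=0)
        for i in range(4):
            for j in range(i + 1, 4):
                half_l1 = np.abs(rel[:, i] - rel[:, j]).sum() / 2
                assert dm[f"s{i}", f"s{j}"] == pytest.approx(half_l1, abs=1e-12)

    def test_identical_samples_distance_zero(self):
        taxa = ["a", "b"]
        tbl = table_from(np.array([[3, 3], [1, 1]]), taxa=taxa)
        tree = TreeNode.read(io.StringIO("(a:1.0,b:1.0);"))
        assert unweighted_unifrac(tbl, tree)["s0", "s1"] == 0.0
        assert weighted_unifrac(tbl, tree)["s0", "s1"] == 0.0

    def test_two_leaf_disjoint_samples(self):
        taxa = ["a", "b"]
        tbl = table_from(np.array([[1, 0], [0, 1]]), taxa=taxa)
        tree = TreeNode.read(io.StringIO("(a:1.0,b:1.0);"))
        assert weighted_unifrac(tbl, tree, normalized=True)["s0", "s1"] == pytest.approx(1.0)
        assert unweighted_unifrac(tbl, tree)["s0", "s1"] == pytest.approx(1.0)

    def test_taxon_absent_from_tree_rejected(self):
        tbl = table_from(np.array([[1, 2], [3, 4]]), taxa=["a", "zzz"])
        tree = TreeNode.read(io.StringIO("(a:1.0,b:1.0);"))
        with pytest.raises(ValueError, match="zzz"):
            unweighted_unifrac(tbl, tree)


class TestPcoa:
    def test_planar_points_reconstructed(self):
        rng = np.random.default_rng(4)
        pts = rng.normal(size=(7, 2))
        dm = DistanceMatrix(squareform(pdist(pts)), ids=[str(i) for i in range(7)])
        res = pcoa(dm, n_axes=2)
        emb = squareform(pdist(res.coordinates.to_numpy()))
        assert np.abs(emb - dm.data).max() < 1e-8

    def test_all_zero_distances(self):
        dm = DistanceMatrix(np.zeros((4, 4)), ids=list("abcd"))
        res = pcoa(dm)
        assert np.allclose(res.coordinates.to_numpy(), 0)

    def test_collinear_points_recover_spacing(self):
        x = np.array([0.0, 1.0, 3.0])
        dm = DistanceMatrix(np.abs(x[:, None] - x[None, :]), ids=list("abc"))
        axis1 = pcoa(dm).coordinates["PC1"].to_numpy()
        gaps = np.abs(np.diff(np.sort(axis1)))
        assert np.allclose(np.sort(gaps), [1.0, 2.0], atol=1e-8)

    def test_eigenvalues_sorted_and_proportions(self):
        rng = np.random.default_rng(5)
        pts = rng.normal(size=(6, 3))
        dm = DistanceMatrix(squareform(pdist(pts)), ids=[str(i) for i in range(6)])
        res = pcoa(dm)
        assert (np.diff(res.eigenvalues) <= 1e-9).all()
        assert res.proportion_explained.sum() <= 1 + 1e-9


class TestPermanova:
    def _dm_with_groups(self, seed=6, n_per=3, shift=0.0):
        rng = np.random.default_rng(seed)
        pts = np.vstack(
            [rng.normal(size=(n_per, 3)), rng.normal(size=(n_per, 3)) + shift]
        )
        ids = [f"s{i}" for i in range(2 * n_per)]
        dm = DistanceMatrix(squareform(pdist(pts)), ids=ids)
        labels = pd.Series(["A"] * n_per + ["B"] * n_per, index=ids, name="grp")
        return dm, labels

    def test_perfect_separation_r2_one(self):
        d = np.array(
            [[0, 0, 1, 1], [0, 0, 1, 1], [1, 1, 0, 0], [1, 1, 0, 0]], dtype=float
        )
        np.fill_diagonal(d, 0)
        dm = DistanceMatrix(d, ids=list("abcd"))
        labels = pd.Series(["A", "A", "B", "B"], index=list("abcd"), name="g")
        res = permanova(dm, labels, n_permutations=99, seed=0)
        assert res.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_all_equal_distances_p_one(self):
        d = np.ones((4, 4)) - np.eye(4)
        dm = DistanceMatrix(d, ids=list("abcd"))
        labels = pd.Series(["A", "A", "B", "B"], index=list("abcd"), name="g")
        res = permanova(dm, labels, n_permutations=99, seed=0)
        assert res.p_value == 1.0

    def test_exact_enumeration_matches_many_random_permutations(self):
        dm, labels = self._dm_with_groups(shift=1.0)
        exact = permanova(dm, labels, exhaustive=True)
        mc = permanova(dm, labels, n_permutations=49999, seed=1)
        assert abs(exact.p_value - mc.p_value) < 0.01

    def test_pseudo_f_matches_skbio_categorical(self):
        dm, labels = self._dm_with_groups(seed=7, n_per=4, shift=0.8)
        ours = permanova(dm, labels, n_permutations=99, seed=0)
        ref = skbio_permanova(dm, labels.to_numpy(), permutations=99)
        assert ours.pseudo_f == pytest.approx(ref["test statistic"], rel=1e-10)

    def test_invariant_to_sample_reordering(self):
        dm, labels = self._dm_with_groups(seed=8, n_per=4, shift=0.5)
        perm = np.random.default_rng(0).permutation(len(dm.ids))
        ids2 = [list(dm.ids)[i] for i in perm]
        dm2 = DistanceMatrix(dm.data[np.ix_(perm, perm)], ids=ids2)
        a = permanova(dm, labels, exhaustive=True)
        b = permanova(dm2, labels, exhaustive=True)
        assert a.pseudo_f == pytest.approx(b.pseudo_f, rel=1e-10)
        assert a.p_value == b.p_value

    def test_numeric_covariate_detects_gradient(self):
        rng = np.random.default_rng(9)
        x = np.linspace(0, 1, 10)
        pts = np.column_stack([x, rng.normal(scale=0.05, size=10)])
        ids = [f"s{i}" for i in range(10)]
        dm = DistanceMatrix(squareform(pdist(pts)), ids=ids)
        cov = pd.Series(x, index=ids, name="gradient")
        res = permanova(dm, cov, n_permutations=199, seed=0)
        assert res.p_value <= 0.01
        assert res.r_squared > 0.5

    def test_small_group_rejected(self):
        dm, labels = self._dm_with_groups()
        labels.iloc[0] = "C"
        with pytest.raises(ValueError, match="size < 2"):
            permanova(dm, labels, n_permutations=99)
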