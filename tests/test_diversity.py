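import io

import numpy as np
import pytest
from scipy.spatial.distance import pdist, squareform
from skbio import TreeNode
from skbio.diversity import beta_diversity

from gutdyn import diversity as dv
from gutdyn.tables_io import CountTable, relative_abundance


def _table(counts, lineage=None):
    counts = np.asarray(counts)
    return CountTable([f"s{i}" for i in range(counts.shape[0])],
                      [f"t{j}" for j in range(counts.shape[1])],
                      counts, lineage or {})


class TestShannon:
    def test_uniform_four_taxa(self):
        h = dv.shannon(_table([[5, 5, 5, 5]]))
        assert h.iloc[0] == pytest.approx(np.log(4), abs=1e-12)

    def test_single_taxon_zero(self):
        assert dv.shannon(_table([[7, 0]])).iloc[0] == 0.0

    def test_half_half(self):
        h = dv.shannon(_table([[3, 3]]))
        assert h.iloc[0] == pytest.approx(np.log(2), abs=1e-12)

    def test_uniform_is_maximal(self):
        rng = np.random.default_rng(0)
        uniform = dv.shannon(_table([[10, 10, 10]])).iloc[0]
        for _ in range(20):
            counts = rng.integers(1, 50, size=3)
            assert dv.shannon(_table([counts])).iloc[0] <= uniform + 1e-12

    def test_bounds(self, small_cohort):
        table = small_cohort[0]
        h = dv.shannon(table)
        assert (h >= 0).all()
        assert (h <= np.log(table.shape[1]) + 1e-12).all()


class TestBrayCurtis:
    def test_identical_samples(self):
        rel = np.array([[0.2, 0.8], [0.2, 0.8]])
        dm = dv.bray_curtis(rel, ["a", "b"])
        assert dm.D[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_disjoint_supports(self):
        rel = np.array([[1.0, 0.0], [0.0, 1.0]])
        assert dv.bray_curtis(rel, ["a", "b"]).D[0, 1] == 1.0

    def test_hand_computed(self):
        rel = np.array([[1.0, 0.0], [0.5, 0.5]])
        assert dv.bray_curtis(rel, ["a", "b"]).D[0, 1] == \
            pytest.approx(0.5, abs=1e-12)

    def test_matches_scipy(self, small_cohort):
        rel = relative_abundance(small_cohort[0])[:20]
        ours = dv.bray_curtis(rel, [str(i) for i in range(20)]).D
        scipy_d = squareform(pdist(rel, metric="braycurtis"))
        np.testing.assert_allclose(ours, scipy_d, atol=1e-12)

    def test_requires_closed_rows(self):
        with pytest.raises(ValueError, match="sum to 1"):
            dv.bray_curtis(np.array([[1.0, 1.0]]), ["a"])


class TestUnifrac:
    CHERRY = "(t0:1.0,t1:1.0);"

    def test_identical_samples_zero(self):
        table = _table([[4, 4], [4, 4]])
        for weighted in (False, True):
            dm = dv.unifrac(table, self.CHERRY, weighted=weighted)
            assert dm.D[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_cherry_disjoint_hand_computed(self):
        # disjoint leaves on an equal-branch cherry: all branch length is
        # unique, so both variants give 1
        table = _table([[5, 0], [0, 5]])
        assert dv.unifrac(table, self.CHERRY, False).D[0, 1] == \
            pytest.approx(1.0)
        assert dv.unifrac(table, self.CHERRY, True).D[0, 1] == \
            pytest.approx(1.0)

    def test_three_leaf_hand_computed(self):
        # ((t0:1,t1:1):1,t2:2); samples {t0} vs {t1}: shared internal
        # branch, unique = 1+1, union = 1+1+1
        tree = "((t0:1.0,t1:1.0):1.0,t2:2.0);"
        table = _table([[3, 0, 0], [0, 3, 0]])
        d = dv.unifrac(table, tree, weighted=False).D[0, 1]
        assert d == pytest.approx(2.0 / 3.0, abs=1e-12)

    def test_taxon_order_invariance(self, small_cohort):
        table, newick = small_cohort[0], small_cohort[2]
        sub = CountTable(table.sample_ids[:6], table.taxon_ids,
                         table.counts[:6], table.lineage)
        d1 = dv.unifrac(sub, newick, weighted=True).D
        perm = np.random.default_rng(1).permutation(len(sub.taxon_ids))
        shuffled = CountTable(
            sub.sample_ids, [sub.taxon_ids[j] for j in perm],
            sub.counts[:, perm], sub.lineage)
        d2 = dv.unifrac(shuffled, newick, weighted=True).D
        np.testing.assert_allclose(d1, d2, atol=1e-12)

    def test_missing_taxon_errors(self):
        with pytest.raises(ValueError, match="missing"):
            dv.unifrac(_table([[1, 1]]), "(t0:1.0,tX:1.0);")

    def test_unweighted_matches_skbio(self, small_cohort):
        table, newick = small_cohort[0], small_cohort[2]
        sub = CountTable(table.sample_ids[:8], table.taxon_ids,
                         table.counts[:8], table.lineage)
        ours = dv.unifrac(sub, newick, weighted=False).D
        tree = TreeNode.read(io.StringIO(newick),
                             convert_underscores=False)
        ref = beta_diversity("unweighted_unifrac", sub.counts,
                             ids=sub.sample_ids, tree=tree,
                             taxa=sub.taxon_ids)
        np.testing.assert_allclose(ours, ref.data, atol=1e-10)

    def test_bounds(self, small_cohort):
        table, newick = small_cohort[0], small_cohort[2]
        sub = CountTable(table.sample_ids[:8], table.taxon_ids,
                         table.counts[:8], table.lineage)
        for weighted in (False, True):
            D = dv.unifrac(sub, newick, weighted=weighted).D
            assert D.min() >= 0 and D.max() <= 1


class TestPcoa:
    def test_line_recovered(self):
        pts = np.array([[0.0], [1.0], [3.0], [6.0]])
        D = squareform(pdist(pts))
        res = dv.pcoa(dv.DistanceMatrix(list("abcd"), D))
        axis1 = res.coordinates[:, 0]
        spacing = np.diff(np.sort(axis1))
        np.testing.assert_allclose(sorted(spacing), [1.0, 2.0, 3.0],
                                   atol=1e-8)

    def test_euclidean_distances_reproduced(self):
        rng = np.random.default_rng(0)
        pts = rng.normal(size=(3, 2))
        D = squareform(pdist(pts))
        res = dv.pcoa(dv.DistanceMatrix(list("abc"), D))
        D_hat = squareform(pdist(res.coordinates))
        np.testing.assert_allclose(D_hat, D, atol=1e-8)

    def test_negative_eigenvalues_reported(self):
        # triangle-inequality violation forces a negative eigenvalue
        D = np.array([[0.0, 1.0, 1.0, 2.5],
                      [1.0, 0.0, 1.0, 1.0],
                      [1.0, 1.0, 0.0, 1.0],
                      [2.5, 1.0, 1.0, 0.0]])
        res = dv.pcoa(dv.DistanceMatrix(list("abcd"), D))
        assert res.eigenvalues.min() < -1e-8


class TestPermanova:
    def _random_dm(self, rng, n=16, shift=0.0):
        pts = rng.normal(size=(n, 3))
        pts[n // 2:] += shift
        return dv.DistanceMatrix(
            [f"s{i}" for i in range(n)], squareform(pdist(pts)))

    def test_separated_clouds_significant(self):
        rng = np.random.default_rng(0)
        dm = self._random_dm(rng, n=20, shift=4.0)
        groups = ["a"] * 10 + ["b"] * 10
        res = dv.permanova(dm, groups, n_perm=199, seed=1)
        assert res.p <= 0.01
        assert res.R2 > 0.3

    def test_reproducible(self):
        rng = np.random.default_rng(2)
        dm = self._random_dm(rng)
        groups = ["a"] * 8 + ["b"] * 8
        p1 = dv.permanova(dm, groups, n_perm=99, seed=5).p
        p2 = dv.permanova(dm, groups, n_perm=99, seed=5).p
        assert p1 == p2

    def test_p_plus_one_convention(self):
        # p can never be below 1/(n_perm+1)
        rng = np.random.default_rng(3)
        dm = self._random_dm(rng, shift=10.0)
        groups = ["a"] * 8 + ["b"] * 8
        res = dv.permanova(dm, groups, n_perm=99, seed=0)
        assert res.p >= 1 / 100

    def test_null_type1_error(self):
        # 120 null replicates; rejection at alpha=0.05 within 3 MC SE
        rng = np.random.default_rng(7)
        rejections = 0
        reps = 120
        for _ in range(reps):
            dm = self._random_dm(rng, n=14)
            groups = ["a"] * 7 + ["b"] * 7
            if dv.permanova(dm, groups, n_perm=99,
                            seed=int(rng.integers(2**31))).p <= 0.05:
                rejections += 1
        rate = rejections / reps
        se = np.sqrt(0.05 * 0.95 / reps)
        assert rate <= 0.05 + 3 * se

    def test_degenerate_groups_error(self):
        rng = np.random.default_rng(1)
        dm = self._random_dm(rng, n=4)
        with pytest.raises(ValueError):
            dv.permanova(dm, ["a", "a", "a", "b"], n_perm=9)

    def test_pairwise_bh_adjustment(self):
        rng = np.random.default_rng(4)
        pts = rng.normal(size=(18, 3))
        pts[6:12] += 3.0
        dm = dv.DistanceMatrix([f"s{i}" for i in range(18)],
                               squareform(pdist(pts)))
        groups = ["a"] * 6 + ["b"] * 6 + ["c"] * 6
        res = dv.permanova_pairwise(dm, groups, n_perm=99, seed=0)
        assert len(res.pairwise) == 3
        for _, _, p, q in res.pairwise:
            assert q >= p - 1e-12


class TestDispersion:
    def test_unequal_spread_detected(self):
        rng = np.random.default_rng(0)
        tight = np.tile(rng.normal(size=(1, 3)), (8, 1)) \
            + rng.normal(scale=0.01, size=(8, 3))
        loose = rng.normal(scale=3.0, size=(8, 3))
        pts = np.vstack([tight, loose])
        dm = dv.DistanceMatrix([f"s{i}" for i in range(16)],
                               squareform(pdist(pts)))
        res = dv.dispersion_test(dm, ["a"] * 8 + ["b"] * 8,
                                 n_perm=199, seed=1)
        assert res.p <= 0.05
        assert res.group_means["a"] < res.group_means["b"]

    def test_nonnegative_spread(self, small_cohort):
        from gutdyn.tables_io import relative_abundance
        rel = relative_abundance(small_cohort[0])[:12]
        dm = dv.bray_curtis(rel, [f"s{i}" for i in range(12)])
        res = dv.dispersion_test(dm, ["a"] * 6 + ["b"] * 6,
                                 n_perm=99, seed=0)
        assert all(v >= 0 for v in res.group_means.values())


class TestBhAdjust:
    def test_monotone_in_p(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(size=30)
        q = dv._bh_adjust(p)
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()
        assert (q >= p - 1e-12).all()
        assert (q <= 1.0).all()
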