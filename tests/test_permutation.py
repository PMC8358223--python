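"""PERMANOVA, Mantel and Procrustes permutation tests."""

import numpy as np
import pytest
from scipy import stats
from scipy.spatial.distance import pdist, squareform

import pantrait as pt


def _euclid_dm(y):
    y = np.asarray(y, dtype=float)
    m = np.abs(y[:, None] - y[None, :])
    return pt.DistanceMatrix(m, [f"s{i}" for i in range(len(y))])


class TestPermanova:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_pseudo_f_equals_classical_anova_f(self, seed):
        rng = np.random.default_rng(seed)
        y = rng.normal(size=21) + np.repeat([0.0, 0.6, 1.0], 7)
        g = np.repeat(list("abc"), 7)
        res = pt.permanova(_euclid_dm(y), g, n_perm=19, seed=0)
        ref = stats.f_oneway(y[:7], y[7:14], y[14:]).statistic
        assert res.statistic == pytest.approx(ref, rel=1e-10)
        assert res.df == (2, 18)

    def test_f_matches_skbio(self, rng):
        skbio = pytest.importorskip("skbio")
        X = rng.random((15, 6)) + 0.05
        g = np.repeat(list("abc"), 5)
        d = pt.bray_curtis(X)
        mine = pt.permanova(d, g, n_perm=9, seed=0)
        ref = skbio.stats.distance.permanova(
            skbio.DistanceMatrix(d.values, d.labels), list(g), permutations=9
        )
        assert mine.statistic == pytest.approx(ref["test statistic"], rel=1e-10)

    def test_r2_partition_sums_to_total(self, rng):
        X = rng.random((12, 5)) + 0.1
        g = np.repeat(list("ab"), 6)
        res = pt.permanova(pt.bray_curtis(X), g, n_perm=9, seed=1)
        total = res.extra["ss_among"] + res.extra["ss_within"]
        assert res.effect == pytest.approx(res.extra["ss_among"] / total)

    def test_invariant_to_label_reordering(self, rng):
        X = rng.random((10, 4)) + 0.1
        labels = [f"s{i}" for i in range(10)]
        g = dict(zip(labels, np.repeat(list("ab"), 5)))
        d = pt.bray_curtis(X, labels=labels)
        shuffled = d.reorder(labels[::-1])
        a = pt.permanova(d, g, n_perm=9, seed=3)
        b = pt.permanova(shuffled, g, n_perm=9, seed=3)
        assert a.statistic == pytest.approx(b.statistic, rel=1e-10)

    def test_duplicated_profiles_give_no_signal(self):
        X = np.tile(np.array([[1.0, 2.0, 3.0], [4.0, 1.0, 2.0]]), (3, 1))
        g = np.array(["a", "a", "a", "b", "b", "b"])
        d = pt.bray_curtis(X[[0, 1, 2, 0, 1, 2]] + 0.0)
        res = pt.permanova(d, g, n_perm=99, seed=0)
        assert res.p_value > 0.5

    def test_seed_reproducibility(self, rng):
        X = rng.random((12, 5)) + 0.1
        g = np.repeat(list("abc"), 4)
        d = pt.bray_curtis(X)
        a = pt.permanova(d, g, n_perm=99, seed=42)
        b = pt.permanova(d, g, n_perm=99, seed=42)
        assert a.p_value == b.p_value
        assert a.p_value >= 1.0 / 100.0

    def test_validation_errors(self, rng):
        X = rng.random((6, 3)) + 0.1
        d = pt.bray_curtis(X)
        with pytest.raises(ValueError):
            pt.permanova(d, ["a"] * 6, n_perm=9, seed=0)  # single group
        with pytest.raises(ValueError):
            pt.permanova(d, ["a", "b"] * 3, n_perm=0, seed=0)
        with pytest.raises(ValueError):
            pt.permanova(d, {f"s{i}": "a" for i in range(5)}, n_perm=9, seed=0)


class TestPairwisePermanova:
    def test_three_groups_give_three_bh_adjusted_results(self, rng):
        X = rng.random((12, 4)) + 0.1
        g = np.repeat(list("abc"), 4)
        res = pt.pairwise_permanova(pt.bray_curtis(X), g, n_perm=49, seed=0)
        assert [r.name for r in res] == ["a_vs_b", "a_vs_c", "b_vs_c"]
        qs = pt.bh_fdr([r.p_value for r in res])
        np.testing.assert_allclose([r.adjusted_p for r in res], qs)

    def test_equal_pvalues_share_q(self):
        np.testing.assert_allclose(pt.bh_fdr([0.02, 0.02, 0.02]), [0.02] * 3)

    def test_planted_pair_detected(self, rng):
        base = rng.random((18, 6)) + 0.5
        base[12:] += 2.0  # group c far away, a and b exchangeable
        g = np.repeat(list("abc"), 6)
        res = pt.pairwise_permanova(pt.bray_curtis(base), g, n_perm=199, seed=1)
        by_name = {r.name: r for r in res}
        assert by_name["a_vs_c"].adjusted_p < 0.05
        assert by_name["b_vs_c"].adjusted_p < 0.05
        assert by_name["a_vs_b"].p_value > 0.05


class TestMantel:
    def test_self_correlation(self, rng):
        d = pt.bray_curtis(rng.random((8, 5)) + 0.1)
        res = pt.mantel(d, d, n_perm=99, seed=0)
        assert res.statistic == pytest.approx(1.0)

    def test_rank_invariance_under_monotone_transform(self, rng):
        X = rng.random((8, 5)) + 0.1
        d1 = pt.bray_curtis(X)
        d2 = pt.DistanceMatrix(np.sqrt(d1.values), d1.labels)
        res = pt.mantel(d1, d2, method="spearman", n_perm=99, seed=0)
        assert res.statistic == pytest.approx(1.0)

    def test_alignment_is_by_label_not_order(self, rng):
        X = rng.random((8, 5)) + 0.1
        d1 = pt.bray_curtis(X)
        d2 = d1.reorder(d1.labels[::-1])
        res = pt.mantel(d1, d2, n_perm=49, seed=0)
        assert res.statistic == pytest.approx(1.0)

    def test_label_mismatch_reported(self, rng):
        d1 = pt.bray_curtis(rng.random((5, 3)) + 0.1, labels=list("abcde"))
        d2 = pt.bray_curtis(rng.random((5, 3)) + 0.1, labels=list("abcdX"))
        with pytest.raises(ValueError, match="X"):
            pt.mantel(d1, d2)

    def test_r_matches_skbio(self, rng):
        skbio = pytest.importorskip("skbio")
        X1 = rng.random((9, 4)) + 0.1
        X2 = rng.random((9, 4)) + 0.1
        d1, d2 = pt.bray_curtis(X1), pt.bray_curtis(X2)
        mine = pt.mantel(d1, d2, method="spearman", n_perm=9, seed=0)
        from skbio.stats.distance import mantel as sk_mantel
        r_ref = sk_mantel(
            skbio.DistanceMatrix(d1.values, d1.labels),
            skbio.DistanceMatrix(d2.values, d2.labels),
            method="spearman", permutations=9, alternative="greater",
        )[0]
        assert mine.statistic == pytest.approx(r_ref, abs=1e-10)


class TestProcrustes:
    def test_rotation_invariance(self, rng):
        X = rng.normal(size=(8, 2))
        th = 1.1
        R = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        res = pt.procrustes_test(X, X @ R, n_perm=49, seed=0)
        assert res.extra["m2"] == pytest.approx(0.0, abs=1e-12)
        assert res.effect == pytest.approx(1.0)

    def test_scale_invariance(self, rng):
        X = rng.normal(size=(7, 3))
        res = pt.procrustes_test(X, X * 7.0, n_perm=49, seed=0)
        assert res.extra["m2"] == pytest.approx(0.0, abs=1e-12)

    def test_few_rows_rejected(self, rng):
        with pytest.raises(ValueError):
            pt.procrustes_test(rng.normal(size=(2, 2)), rng.normal(size=(2, 2)))

    def test_m2_matches_skbio_procrustes(self, rng):
        from scipy.spatial import procrustes as scipy_procrustes

        X = rng.normal(size=(9, 3))
        Y = X + 0.3 * rng.normal(size=(9, 3))
        mine = pt.procrustes_test(X, Y, n_perm=9, seed=0)
        _, _, disparity = scipy_procrustes(X, Y)
        assert mine.extra["m2"] == pytest.approx(disparity, rel=1e-8)
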