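"""Ward clustering, dendrogram cophenetics, multiscale bootstrap support."""

import itertools

import numpy as np
import pytest
from scipy.cluster import hierarchy as sch
from scipy.spatial.distance import pdist, squareform

import pantrait as pt
from pantrait.multivariate import _fast_tree_clusters, cophenetic_from_dendrogram, ward_cluster


def _euclid(X):
    return pt.DistanceMatrix(squareform(pdist(X)), [f"s{i}" for i in range(len(X))])


class TestWard:
    def test_top_split_separates_blobs(self, rng):
        X = np.vstack([rng.normal(0, 0.1, (3, 2)), rng.normal(5, 0.1, (3, 2))])
        dend = ward_cluster(_euclid(X))
        clusters = dend.clusters()
        assert frozenset({"s0", "s1", "s2"}) in clusters
        assert frozenset({"s3", "s4", "s5"}) in clusters

    def test_heights_match_scipy_ward(self, rng):
        X = rng.normal(size=(14, 5))
        dend = ward_cluster(_euclid(X))
        Z = sch.linkage(pdist(X), method="ward")
        np.testing.assert_allclose(np.sort(dend.heights), np.sort(Z[:, 2]), rtol=1e-10)

    def test_four_point_merge_sequence_vs_exhaustive_ward(self):
        # hand instance: two tight pairs; Ward must merge {a,b} and {c,d}
        # first, then join them.  The exhaustive check evaluates the Ward
        # objective (total within-cluster sum of squares) over all merge
        # sequences.
        X = np.array([[0.0, 0], [0.4, 0], [10, 0], [10.5, 0]])
        dend = ward_cluster(_euclid(X))
        sets = dend.merge_sets()
        assert sets[0] == frozenset({"s0", "s1"})
        assert sets[1] == frozenset({"s2", "s3"})

        def wss(groups):
            return sum(
                ((X[list(g)] - X[list(g)].mean(axis=0)) ** 2).sum() for g in groups
            )

        # the greedy first merge must be the pair minimizing the WSS increase
        best_pair = min(
            itertools.combinations(range(4), 2),
            key=lambda p: wss([set(p)] + [{k} for k in range(4) if k not in p]),
        )
        assert frozenset(f"s{i}" for i in best_pair) == sets[0]

    def test_input_order_invariance(self, rng):
        X = rng.normal(size=(8, 3))
        d = _euclid(X)
        perm = rng.permutation(8)
        d2 = d.reorder([f"s{i}" for i in perm])
        t1 = set(ward_cluster(d).clusters())
        t2 = set(ward_cluster(d2).clusters())
        assert t1 == t2

    def test_ward_d_variant_differs_on_heights(self, rng):
        X = rng.normal(size=(6, 3))
        d = _euclid(X)
        h2 = ward_cluster(d, variant="ward.D2").heights
        h1 = ward_cluster(d, variant="ward.D").heights
        assert not np.allclose(np.sort(h1), np.sort(h2))

    def test_single_sample_rejected(self):
        with pytest.raises(ValueError):
            ward_cluster(pt.DistanceMatrix(np.zeros((1, 1)), ["a"]))

    def test_fast_path_matches_ward_cluster(self, rng):
        # the bootstrap inner loop (scipy pdist + linkage) must produce the
        # same cluster sets as the from-scratch implementation
        for _ in range(5):
            X = rng.random((9, 12)) + 0.05
            mine = {
                frozenset(int(l[1:]) for l in c)
                for c in ward_cluster(pt.bray_curtis(X)).clusters()
            }
            fast = set(_fast_tree_clusters(X))
            assert mine == fast


class TestCopheneticDendrogram:
    def test_chain_merge_heights(self):
        # {A,B} at 1 then {AB,C} at 2 -> d(A,C) = 2
        Z = np.array([[0.0, 1.0, 1.0, 2.0], [2.0, 3.0, 2.0, 3.0]])
        dend = pt.Dendrogram(Z, ["A", "B", "C"])
        d = cophenetic_from_dendrogram(dend)
        df = d.to_dataframe()
        assert df.loc["A", "B"] == 1.0
        assert df.loc["A", "C"] == 2.0

    def test_ultrametric_inequality(self, rng):
        X = rng.normal(size=(10, 4))
        d = cophenetic_from_dendrogram(ward_cluster(_euclid(X)))
        v = d.values
        for i, j, k in itertools.permutations(range(10), 3):
            assert v[i, k] <= max(v[i, j], v[j, k]) + 1e-12

    def test_matches_scipy_cophenet(self, rng):
        X = rng.normal(size=(11, 5))
        dend = ward_cluster(_euclid(X))
        mine = cophenetic_from_dendrogram(dend).values
        ref = squareform(sch.cophenet(sch.linkage(pdist(X), method="ward")))
        np.testing.assert_allclose(mine, ref, rtol=1e-10)

    def test_dendrogram_newick_export_round_trips(self, rng):
        X = rng.normal(size=(6, 3))
        dend = ward_cluster(_euclid(X))
        tree = dend.to_phylotree()
        assert set(tree.tip_labels) == set(dend.labels)
        # root-to-tip distance equals the root height in an ultrametric tree
        root_height = dend.heights[-1]
        dists = pt.patristic_root_distances(tree)
        np.testing.assert_allclose(list(dists.values()), root_height, rtol=1e-8)


class TestMultiscaleBootstrap:
    def test_separated_blocks_reach_full_support(self, rng):
        X = np.abs(np.vstack([rng.normal(8, 0.05, (4, 18)), rng.normal(1, 0.05, (4, 18))]))
        sup = pt.multiscale_bootstrap_support(X, n_boot=300, seed=0)
        key = frozenset(f"s{i}" for i in range(4))
        a = sup.table[sup.table["cluster"] == key].iloc[0]
        assert a["au"] == pytest.approx(1.0, abs=1e-9)
        assert a["bp"] == pytest.approx(1.0, abs=1e-9)

    def test_single_scale_bp_is_plain_bootstrap_proportion(self, rng):
        # with scales {1.0, 1.0001} the fitted machinery is bypassed for BP:
        # the reported BP must agree with an independently coded plain
        # bootstrap to Monte-Carlo accuracy
        X = rng.random((7, 20)) + 0.05
        B = 400
        sup = pt.multiscale_bootstrap_support(X, scales=[1.0, 1.0], n_boot=B, seed=5)
        # independent direct bootstrap
        rng2 = np.random.default_rng(999)
        counts = {tuple(sorted(c)): 0 for c in sup.table["cluster"]}
        idx = {f"s{i}": i for i in range(7)}
        obs = {tuple(sorted(idx[l] for l in c)): tuple(sorted(c))
               for c in sup.table["cluster"]}
        for _ in range(B):
            cols = rng2.integers(0, 20, size=20)
            reps = set(_fast_tree_clusters(X[:, cols]))
            for key, name in obs.items():
                if frozenset(key) in reps:
                    counts[name] += 1
        for name, cnt in counts.items():
            bp_direct = cnt / B
            bp_mine = float(
                sup.table.loc[sup.table["cluster"].map(lambda c: tuple(sorted(c)) == name), "bp"].iloc[0]
            )
            assert abs(bp_mine - bp_direct) < 0.12  # two independent B=400 draws

    def test_tiny_scale_dropped_with_warning(self, rng):
        X = rng.random((5, 3)) + 0.1
        sup = pt.multiscale_bootstrap_support(
            X, scales=[0.3, 0.8, 1.0, 1.2], n_boot=50, seed=1
        )
        assert 0.3 not in sup.scales  # round(3*0.3) = 1 < 2 features

    def test_input_validation(self, rng):
        with pytest.raises(ValueError):
            pt.multiscale_bootstrap_support(rng.random((3, 5)) + 0.1, n_boot=10, seed=0)
        with pytest.raises(ValueError):
            pt.multiscale_bootstrap_support(rng.random((6, 1)) + 0.1, n_boot=10, seed=0)
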