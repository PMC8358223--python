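"""Core/accessory partitioning, diversity indices and exact tests."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import pantrait as pt
from pantrait.datatypes import AlignmentBlock, PresenceAbsenceMatrix
from pantrait.pangenome import _table_prob, fisher_exact_rx2


def _pa(cells, genes=None, strains=None, ann=None):
    cells = np.asarray(cells)
    genes = genes or [f"g{i}" for i in range(cells.shape[0])]
    strains = strains or [f"s{i}" for i in range(cells.shape[1])]
    return PresenceAbsenceMatrix(pd.DataFrame(cells, index=genes, columns=strains), ann)


class TestPartition:
    def test_gene_in_all_strains_is_core(self):
        pa = _pa([[1, 1, 1], [1, 0, 0], [0, 0, 0]])
        parts = pt.partition_pangenome(pa, {f"s{i}": "sp" for i in range(3)})
        p = parts[0]
        assert p.core_genes == ["g0"]
        assert p.accessory_genes == ["g1"]
        assert p.per_strain_accessory == {"s0": 1, "s1": 0, "s2": 0}
        assert p.n_pangenome == 2  # g2 absent everywhere is not in the pangenome

    def test_random_matrix_matches_per_gene_scan_oracle(self, rng):
        cells = rng.integers(0, 2, size=(200, 5))
        species = {f"s{i}": ("A" if i < 3 else "B") for i in range(5)}
        parts = {p.species: p for p in pt.partition_pangenome(_pa(cells), species)}
        for sp, idx in (("A", [0, 1, 2]), ("B", [3, 4])):
            sub = cells[:, idx]
            core = {f"g{i}" for i in range(200) if sub[i].all()}
            acc = {f"g{i}" for i in range(200) if sub[i].any() and not sub[i].all()}
            assert set(parts[sp].core_genes) == core
            assert set(parts[sp].accessory_genes) == acc

    def test_presence_bookkeeping_invariant(self, rng):
        # per strain: core + strain accessory = column sum within the species
        cells = rng.integers(0, 2, size=(120, 4))
        species = {f"s{i}": "sp" for i in range(4)}
        (p,) = pt.partition_pangenome(_pa(cells), species)
        col_sums = cells.sum(axis=0)
        for k, s in enumerate(p.strain_ids):
            assert p.n_core + p.per_strain_accessory[s] == col_sums[k]

    def test_single_strain_species_skipped(self, rng):
        cells = rng.integers(0, 2, size=(10, 3))
        parts = pt.partition_pangenome(
            _pa(cells), {"s0": "solo", "s1": "pair", "s2": "pair"}
        )
        assert [p.species for p in parts] == ["pair"]

    def test_core_fraction_threshold(self):
        cells = [[1, 1, 1, 0], [1, 1, 1, 1]]
        pa = _pa(cells)
        strict = pt.partition_pangenome(pa, {f"s{i}": "sp" for i in range(4)})[0]
        relaxed = pt.partition_pangenome(
            pa, {f"s{i}": "sp" for i in range(4)}, core_fraction=0.75
        )[0]
        assert strict.core_genes == ["g1"]
        assert set(relaxed.core_genes) == {"g0", "g1"}


class TestDistributionIndex:
    def test_all_core_limit(self):
        pa = _pa(np.ones((300, 3), dtype=int))
        (p,) = pt.partition_pangenome(pa, {f"s{i}": "sp" for i in range(3)})
        assert (pt.distribution_index(p) == 1.0).all()

    def test_balanced_strain_gives_zero(self):
        p = pt.PangenomePartition(
            species="sp", strain_ids=["a", "b"],
            core_genes=[f"c{i}" for i in range(150)],
            accessory_genes=[f"x{i}" for i in range(350)],
            per_strain_accessory={"a": 150, "b": 10},
        )
        d = pt.distribution_index(p)
        assert d["a"] == pytest.approx((150 - 150) / 500)
        assert d["b"] == pytest.approx((150 - 10) / 500)

    def test_direct_formula(self):
        p = pt.PangenomePartition(
            species="sp", strain_ids=["a"],
            core_genes=[f"c{i}" for i in range(200)],
            accessory_genes=[f"x{i}" for i in range(200)],
            per_strain_accessory={"a": 100},
        )
        assert pt.distribution_index(p)["a"] == pytest.approx(0.25)

    def test_zero_pangenome_rejected(self):
        p = pt.PangenomePartition("sp", ["a"], [], [], {"a": 0})
        with pytest.raises(ValueError):
            pt.distribution_index(p)

    def test_gene_relabeling_invariance(self, rng):
        cells = rng.integers(0, 2, size=(50, 4))
        sp = {f"s{i}": "sp" for i in range(4)}
        (p1,) = pt.partition_pangenome(_pa(cells), sp)
        perm = rng.permutation(50)
        (p2,) = pt.partition_pangenome(
            _pa(cells[perm], genes=[f"h{i}" for i in range(50)]), sp
        )
        assert pt.distribution_index(p1).equals(pt.distribution_index(p2))


class TestDiversity:
    def test_identical_sequences_zero_entropy(self):
        aln = AlignmentBlock(["a", "b", "c"], ["MKV", "MKV", "MKV"], "aa")
        assert pt.residue_diversity(aln) == 0.0

    def test_half_split_column(self):
        # one column split 50/50, nine invariant, L = 10 -> mean 0.1 bits
        seqs = ["A" * 10, "A" * 9 + "C"]
        aln = AlignmentBlock(["a", "b"], seqs, "aa")
        assert pt.residue_diversity(aln) == pytest.approx(0.1)

    def test_matches_columnwise_tally_oracle(self, rng):
        from collections import Counter

        seqs = ["".join(rng.choice(list("ACDE-"), 40)) for _ in range(6)]
        aln = AlignmentBlock([f"s{i}" for i in range(6)], seqs, "aa")
        mine = pt.residue_diversity(aln)
        cols = []
        for j in range(40):
            res = [s[j] for s in seqs if s[j] != "-"]
            if not res:
                continue
            cnt = Counter(res)
            n = sum(cnt.values())
            cols.append(-sum(c / n * math.log2(c / n) for c in cnt.values()))
        assert mine == pytest.approx(np.mean(cols))

    def test_gaps_excluded_from_distribution(self):
        aln = AlignmentBlock(["a", "b", "c"], ["A-", "A-", "AC"], "aa")
        # column 2 has residues {C} only after gap removal -> entropy 0
        assert pt.residue_diversity(aln) == 0.0

    def test_pi_identical_pair(self):
        aln = AlignmentBlock(["a", "b"], ["ACGT" * 25, "ACGT" * 25], "nt")
        assert pt.nucleotide_diversity(aln) == 0.0

    def test_pi_two_of_hundred(self):
        s1 = "A" * 100
        s2 = "C" * 2 + "A" * 98
        aln = AlignmentBlock(["a", "b"], [s1, s2], "nt")
        assert pt.nucleotide_diversity(aln) == pytest.approx(0.02)

    def test_pi_three_sequences_is_mean_of_pairs(self, rng):
        seqs = ["".join(rng.choice(list("ACGT"), 60)) for _ in range(3)]
        aln = AlignmentBlock(["a", "b", "c"], seqs, "nt")
        pair_vals = []
        for i, j in itertools.combinations(range(3), 2):
            sub = AlignmentBlock(["x", "y"], [seqs[i], seqs[j]], "nt")
            pair_vals.append(pt.nucleotide_diversity(sub))
        assert pt.nucleotide_diversity(aln) == pytest.approx(np.mean(pair_vals))

    def test_pi_pairwise_gap_deletion(self):
        aln = AlignmentBlock(["a", "b"], ["AC-T", "ACGT"], "nt")
        assert pt.nucleotide_diversity(aln) == 0.0


def _brute_force_rx2_p(table):
    """Naive Freeman-Halton: full itertools enumeration of first-column fills."""
    t = np.asarray(table, dtype=int)
    rows = t.sum(axis=1)
    c1 = t[:, 0].sum()
    p_obs = _table_prob(t)
    total = 0.0
    for fill in itertools.product(*[range(r + 1) for r in rows]):
        if sum(fill) != c1:
            continue
        cand = np.column_stack([fill, rows - np.array(fill)])
        p = _table_prob(cand)
        if p <= p_obs * (1 + 1e-7):
            total += p
    return min(1.0, total)


class TestFisher:
    def test_two_by_two_worked_example(self):
        r = fisher_exact_rx2([[5, 0], [0, 5]])
        assert r.p_value == pytest.approx(2 / 252)

    def test_degenerate_margin_p_one(self):
        r = fisher_exact_rx2([[5, 0], [6, 0], [13, 0]])
        assert r.p_value == pytest.approx(1.0)

    def test_matches_scipy_on_2x2(self, rng):
        for _ in range(20):
            t = rng.integers(0, 9, size=(2, 2))
            if t.sum() == 0:
                continue
            mine = fisher_exact_rx2(t).p_value
            ref = stats.fisher_exact(t)[1]
            assert mine == pytest.approx(ref, abs=1e-10)

    def test_matches_brute_force_on_rx2(self, rng):
        for _ in range(15):
            r = rng.integers(2, 5)
            t = rng.integers(0, 5, size=(r, 2))
            if t.sum() == 0 or (t.sum(axis=1) == 0).any():
                continue
            assert fisher_exact_rx2(t).p_value == pytest.approx(
                _brute_force_rx2_p(t), abs=1e-10
            )

    def test_monte_carlo_fallback_close_to_exact(self):
        t = np.array([[4, 8], [9, 2], [3, 6]])
        exact = fisher_exact_rx2(t).p_value
        mc = fisher_exact_rx2(t, enum_max=10, n_mc=40000, seed=0)
        assert mc.extra["method"] == "monte-carlo"
        assert abs(mc.p_value - exact) < 4 * mc.extra["mc_se"] + 1e-3

    def test_negative_cells_rejected(self):
        with pytest.raises(ValueError):
            fisher_exact_rx2([[1, -1], [0, 2]])


class TestIncidence:
    def test_min_genomes_filter(self):
        cells = np.array([
            [1, 1, 0, 0, 0, 0],  # 2 genomes -> filtered out
            [1, 1, 1, 0, 0, 0],  # kept
        ])
        sp = {f"s{i}": ("A" if i < 3 else "B") for i in range(6)}
        res = pt.orthogroup_incidence_test(_pa(cells), sp, min_genomes=3)
        assert [r.name for r in res] == ["g1"]

    def test_everywhere_present_orthogroup_p_one(self):
        cells = np.ones((1, 6), dtype=int)
        sp = {f"s{i}": ("A" if i < 3 else "B") for i in range(6)}
        res = pt.orthogroup_incidence_test(_pa(cells), sp, min_genomes=3)
        assert res[0].p_value == pytest.approx(1.0)

    def test_species_specific_orthogroup_significant(self):
        cells = np.array([[1, 1, 1, 1, 1, 0, 0, 0, 0, 0]] * 3)
        sp = {f"s{i}": ("A" if i < 5 else "B") for i in range(10)}
        res = pt.orthogroup_incidence_test(_pa(cells), sp)
        assert all(r.p_value == pytest.approx(2 / 252) for r in res)
        # BH over three identical p-values leaves them unchanged
        assert all(r.adjusted_p == pytest.approx(2 / 252) for r in res)


class TestEnrichment:
    def _partition(self, acc_ann, core_ann):
        ann = {}
        acc, core = [], []
        for i, (sub, role) in enumerate(acc_ann):
            g = f"a{i}"
            acc.append(g)
            ann[g] = (sub, role)
        for i, (sub, role) in enumerate(core_ann):
            g = f"c{i}"
            core.append(g)
            ann[g] = (sub, role)
        p = pt.PangenomePartition("sp", ["x", "y"], core, acc,
                                  {"x": len(acc), "y": 0})
        return p, ann

    def test_worked_table(self):
        acc = [("S", f"r{i}") for i in range(8)] + [("other", f"o{i}") for i in range(12)]
        core = [("S", f"cr{i}") for i in range(10)] + [("other", f"co{i}") for i in range(170)]
        p, ann = self._partition(acc, core)
        res = {r.name: r for r in pt.accessory_enrichment(p, ann)}
        r = res["S"]
        assert r.effect == pytest.approx((8 * 170) / (12 * 10))  # 11.33
        expected_p = stats.hypergeom.sf(7, 200, 18, 20)
        assert r.p_value == pytest.approx(expected_p, rel=1e-10)

    def test_proportional_subsystem_not_enriched(self):
        acc = [("S", f"r{i}") for i in range(2)] + [("other", f"o{i}") for i in range(18)]
        core = [("S", f"cr{i}") for i in range(20)] + [("other", f"co{i}") for i in range(180)]
        p, ann = self._partition(acc, core)
        r = {x.name: x for x in pt.accessory_enrichment(p, ann)}["S"]
        assert r.effect == pytest.approx(1.0)
        assert r.p_value >= 0.5

    def test_empty_accessory_yields_no_tests(self):
        p, ann = self._partition([], [("S", "r")])
        assert pt.accessory_enrichment(p, ann) == []

    def test_haldane_correction_on_zero_cell(self):
        acc = [("S", f"r{i}") for i in range(3)]
        core = [("other", f"co{i}") for i in range(30)]
        p, ann = self._partition(acc, core)
        r = {x.name: x for x in pt.accessory_enrichment(p, ann)}["S"]
        assert np.isfinite(r.effect) and r.effect > 1


class TestBhFdr:
    def test_step_up_worked_example(self):
        np.testing.assert_allclose(pt.bh_fdr([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_single_and_degenerate(self):
        assert pt.bh_fdr([0.2])[0] == pytest.approx(0.2)
        np.testing.assert_allclose(pt.bh_fdr([1.0, 1.0]), 1.0)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            pt.bh_fdr([0.1, 1.2])

    def test_matches_statsmodels(self, rng):
        from statsmodels.stats.multitest import multipletests

        p = rng.random(40)
        ref = multipletests(p, method="fdr_bh")[1]
        np.testing.assert_allclose(pt.bh_fdr(p), ref, atol=1e-12)

    def test_monotone_in_sorted_order(self, rng):
        p = rng.random(25)
        q = pt.bh_fdr(p)
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()
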