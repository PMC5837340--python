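"""Clade tables, MCC/MAP/MRC construction, and marginal age annotation."""

import itertools

import numpy as np
import pytest

from cladesum import (
    CladeTable,
    TreeSample,
    annotate_ages,
    build_clade_table,
    extract_clades,
    hpd_interval,
    map_tree,
    mcc_tree,
    mrc_tree,
    parse_newick,
    perturbation_sample,
)
from oracles import (
    brute_force_hpd,
    brute_force_mcc,
    brute_force_topology_frequencies,
)


def _sample_of(newicks, burnin=0.0):
    return TreeSample(trees=[parse_newick(s) for s in newicks], burnin_fraction=burnin)


class TestCladeTable:
    def test_identical_trees_all_pp_one(self):
        sample = _sample_of(["((A:1,B:1):1,(C:1,D:1):1);"] * 4)
        table = build_clade_table(sample)
        assert table.sample_size == 4
        assert set(table.entries.values()) == {1.0}
        assert len(table) == 3

    def test_partial_occurrence_counts(self):
        sample = _sample_of(
            ["((A:1,B:1):1,(C:1,D:1):1);"] * 3 + ["((A:1,C:1):1,(B:1,D:1):1);"]
        )
        table = build_clade_table(sample)
        assert table.pp(frozenset("AB")) == pytest.approx(0.75)
        assert table.pp(frozenset("AC")) == pytest.approx(0.25)
        assert table.pp(frozenset("ABCD")) == pytest.approx(1.0)

    def test_burnin_removed_before_counting(self):
        sample = _sample_of(
            ["((A:1,C:1):1,(B:1,D:1):1);"] + ["((A:1,B:1):1,(C:1,D:1):1);"] * 3,
            burnin=0.25,
        )
        table = build_clade_table(sample)
        assert table.sample_size == 3
        assert table.pp(frozenset("AC")) == 0.0


class TestMcc:
    def test_all_identical_scores_n_minus_one(self):
        sample = _sample_of(["((A:1,B:1):1,(C:1,D:1):1);"] * 4)
        cons = mcc_tree(sample, mode="sum")
        assert cons.metadata["score"] == pytest.approx(3.0)
        assert extract_clades(cons.tree) == extract_clades(sample.trees[0])

    def test_majority_topology_wins_both_modes(self):
        # 5 trees over 5 tips, two competing topologies (3 vs 2 occurrences)
        t_major = "(((A:1,B:1):1,C:2):1,(D:1,E:1):2);"
        t_minor = "(((A:1,C:1):1,B:2):1,(D:1,E:1):2);"
        sample = _sample_of([t_major, t_minor, t_major, t_minor, t_major])
        expected = extract_clades(parse_newick(t_major))
        for mode in ("sum", "product"):
            cons = mcc_tree(sample, mode=mode)
            assert extract_clades(cons.tree) == expected

    @pytest.mark.parametrize("mode", ["sum", "product"])
    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_rescoring(self, mode, seed, serial_tree):
        sample = perturbation_sample(serial_tree, n_trees=40, diffusion=2.0, seed=seed)
        table = build_clade_table(sample)
        cons = mcc_tree(sample, table, mode=mode)
        idx, score = brute_force_mcc(sample.post_burnin, table.entries, mode)
        assert cons.metadata["score"] == pytest.approx(score)
        assert extract_clades(cons.tree) == extract_clades(sample.post_burnin[idx])


class TestMap:
    def test_modal_topology_wins(self):
        t1 = "((A:1,B:1):1,(C:1,D:1):1);"
        t2 = "((A:1,C:1):1,(B:1,D:1):1);"
        sample = _sample_of([t1, t2, t1, t2, t1])
        cons = map_tree(sample)
        assert extract_clades(cons.tree) == extract_clades(parse_newick(t1))
        assert cons.metadata["topology_frequency"] == pytest.approx(0.6)

    @pytest.mark.parametrize("seed", range(5))
    def test_frequency_is_maximal_by_tabulation(self, seed, serial_tree):
        sample = perturbation_sample(serial_tree, n_trees=50, diffusion=1.0, seed=seed + 50)
        cons = map_tree(sample)
        freqs = brute_force_topology_frequencies(sample.post_burnin)
        won = freqs[frozenset(extract_clades(cons.tree))]
        assert won == pytest.approx(max(freqs.values()))


class TestMrc:
    def test_toy_table_hand_assembly(self):
        table = CladeTable(
            entries={frozenset("ABCD"): 1.0, frozenset("AB"): 0.6,
                     frozenset("CD"): 0.4, frozenset("AC"): 0.4},
            sample_size=10,
        )
        cons = mrc_tree(table)
        assert extract_clades(cons.tree) == {frozenset("ABCD"), frozenset("AB")}
        root_children = cons.tree.root.children
        assert len(root_children) == 3  # (A,B) plus the two loose tips

    def test_pp_exactly_half_is_excluded(self):
        table = CladeTable(
            entries={frozenset("ABCD"): 1.0, frozenset("AB"): 0.5, frozenset("CD"): 0.51},
            sample_size=100,
        )
        cons = mrc_tree(table)
        assert frozenset("AB") not in extract_clades(cons.tree)
        assert frozenset("CD") in extract_clades(cons.tree)

    def test_identical_sample_fully_resolved(self):
        sample = _sample_of(["(((A:1,B:1):1,C:2):1,D:3);"] * 6)
        cons = mrc_tree(build_clade_table(sample))
        assert extract_clades(cons.tree) == extract_clades(sample.trees[0])
        assert all(pp == 1.0 for pp in cons.clade_support.values())

    @pytest.mark.parametrize("seed", range(8))
    def test_majority_clades_exactly_and_compatible(self, seed, serial_tree):
        sample = perturbation_sample(serial_tree, n_trees=30, diffusion=3.0, seed=seed + 100)
        table = build_clade_table(sample)
        cons = mrc_tree(table)
        majority = {c for c, pp in table.entries.items() if pp > 0.5}
        got = extract_clades(cons.tree)
        assert got == majority | {serial_tree.tip_set}
        for a, b in itertools.combinations(got, 2):
            assert a <= b or b <= a or not (a & b)  # pairwise compatible
        assert all(pp > 0.5 for c, pp in cons.clade_support.items()
                   if c != serial_tree.tip_set)


class TestAnnotateAges:
    def test_identical_trees_zero_width_hpd(self):
        sample = _sample_of(["((A:1,B:1):1,(C:1,D:1):1);"] * 5)
        cons = annotate_ages(mrc_tree(build_clade_table(sample)), sample)
        for clade, s in cons.clade_age_summary.items():
            assert s["n"] == 5
            assert s["hpd_lower"] == pytest.approx(s["hpd_upper"])
            assert s["mean"] == pytest.approx(s["hpd_lower"])
        assert cons.negative_branches == []

    def test_hpd_shortest_window(self):
        values = list(range(1, 101))
        lo, hi = hpd_interval(values, 0.95)
        assert hi - lo == 94  # any 95-value window of consecutive integers
        blo, bhi = brute_force_hpd(values, 0.95)
        assert (hi - lo) == pytest.approx(bhi - blo)

    @pytest.mark.parametrize("seed", range(10))
    def test_hpd_matches_exhaustive_search(self, seed):
        rng = np.random.default_rng(seed)
        values = rng.gamma(2.0, 1.0, size=rng.integers(5, 60))
        lo, hi = hpd_interval(values, 0.95)
        blo, bhi = brute_force_hpd(values, 0.95)
        assert lo == pytest.approx(blo)
        assert hi == pytest.approx(bhi)

    def test_contributing_tree_counts(self, serial_tree):
        sample = perturbation_sample(serial_tree, n_trees=40, diffusion=2.0, seed=3)
        table = build_clade_table(sample)
        cons = annotate_ages(mrc_tree(table), sample)
        for clade, s in cons.clade_age_summary.items():
            expected = round(table.pp(clade) * table.sample_size)
            assert s["n"] == expected

    def test_negative_branch_flagged_not_repaired(self):
        # The MCC winner contains clade ABC (pp 0.6, always young); its child
        # AB (pp 1.0) is old in the competing topology, so AB's marginal mean
        # age exceeds ABC's and the implied branch is negative.
        t1 = "(((A:0.1,B:0.1):0.05,C:0.15):2.85,D:3);"   # AB age 0.1, ABC age 0.15
        t2 = "((A:2,B:2):1,(C:0.5,D:0.5):2.5);"          # AB age 2
        sample = _sample_of([t1] * 6 + [t2] * 4)
        cons = annotate_ages(mcc_tree(sample), sample)
        assert extract_clades(cons.tree) == extract_clades(parse_newick(t1))
        assert cons.clade_age_summary[frozenset("AB")]["mean"] == pytest.approx(0.86)
        assert cons.clade_age_summary[frozenset("ABC")]["mean"] == pytest.approx(0.15)
        assert (frozenset("ABC"), frozenset("AB")) in cons.negative_branches
        # ages are reported as-is: the annotated tree keeps the inversion
        ages = cons.tree.clade_ages()
        assert ages[frozenset("AB")] > ages[frozenset("ABC")]

    def test_mean_age_equals_marginal_mean(self, serial_tree):
        sample = perturbation_sample(serial_tree, n_trees=25, diffusion=1.0, seed=9)
        cons = annotate_ages(mcc_tree(sample), sample)
        for clade, s in cons.clade_age_summary.items():
            ages = [t.clade_ages()[clade] for t in sample.post_burnin
                    if clade in t.clade_ages()]
            assert s["mean"] == pytest.approx(float(np.mean(ages)))

    def test_annotated_newick_contains_metadata(self, serial_tree):
        sample = perturbation_sample(serial_tree, n_trees=10, diffusion=1.0, seed=2)
        cons = annotate_ages(mcc_tree(sample), sample)
        text = cons.newick(annotated=True)
        assert "posterior=" in text and "age_95%HPD=" in text
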