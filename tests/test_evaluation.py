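"""Accuracy scoring, valid-but-unrepresented clades, experiment runner."""

import numpy as np
import pytest

from cladesum import (
    ExperimentConfig,
    McmcConfig,
    SimulationConfig,
    TreeSample,
    build_clade_table,
    extract_clades,
    map_tree,
    mcc_tree,
    mrc_tree,
    parse_newick,
    perturbation_sample,
    run_experiment,
    score_consensus,
    unrepresented_clades,
)
from conftest import random_time_tree
from oracles import brute_force_accuracy


class TestScoreConsensus:
    def test_identity_on_fully_resolved_36_tips(self):
        from cladesum import simulate_serial_tree

        truth = simulate_serial_tree(SimulationConfig(seed=21))
        report = score_consensus(truth.copy(), truth)
        assert report.n_clades == 35
        assert report.n_correct == 35
        assert report.n_incorrect == 0
        assert report.score == 35
        assert report.pct_incorrect == 0.0

    def test_star_tree_only_root_counts(self):
        truth = parse_newick("((A:1,B:1):1,(C:1,D:1):1);")
        star = parse_newick("(A:1,B:1,C:1,D:1);")
        report = score_consensus(star, truth)
        assert (report.n_clades, report.n_correct, report.n_incorrect) == (1, 1, 0)
        assert report.score == 1

    def test_six_tip_worked_case(self):
        truth = parse_newick("((A:1,B:1):2,((C:1,D:1):1,(E:1,F:1):1):1);")
        cons = parse_newick("((A:1,C:1):2,((B:1,D:1):1,(E:1,F:1):1):1);")
        report = score_consensus(cons, truth)
        # EF and the root are correct; AC, BD and BDEF are not
        assert report.n_clades == 5
        assert report.n_correct == 2
        assert report.n_incorrect == 3
        assert report.score == -1

    def test_tip_set_mismatch_errors(self):
        truth = parse_newick("((A:1,B:1):1,C:2);")
        other = parse_newick("((A:1,B:1):1,X:2);")
        with pytest.raises(ValueError):
            score_consensus(other, truth)

    @pytest.mark.parametrize("seed", range(20))
    def test_agrees_with_independent_set_comparison(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 9))
        truth = random_time_tree(n, seed=seed)
        cons_sample = perturbation_sample(truth, n_trees=1, diffusion=3.0, seed=seed + 7)
        cons = cons_sample.trees[0]
        report = score_consensus(cons, truth)
        correct, incorrect = brute_force_accuracy(
            extract_clades(cons), extract_clades(truth)
        )
        assert (report.n_correct, report.n_incorrect) == (correct, incorrect)
        assert report.n_correct + report.n_incorrect == report.n_clades


class TestUnrepresentedClades:
    def test_mrc_target_above_half_is_empty(self, serial_tree):
        sample = perturbation_sample(serial_tree, n_trees=30, diffusion=3.0, seed=1)
        table = build_clade_table(sample)
        report = unrepresented_clades(table, mrc_tree(table), criterion="above_half")
        assert report.clades == []
        assert report.n_mrc_missing == 0

    def test_constructed_high_pp_clade_missing_from_mcc(self):
        # Clade X = {X1, X2} is in 8 of 10 trees (pp 0.8) but never co-occurs
        # with any clade of the remaining topology, which appears twice and
        # has eight pp-0.2 clades (credibility 2.6 beats the X-trees' 2.5), so
        # the MCC tree excludes a clade of pp 0.8.
        others = [f"t{i}" for i in range(1, 9)]

        def caterpillar(core, order):
            tree = core
            for tip in order:
                tree = f"({tree}:1,{tip}:1)"
            return tree + ";"

        x_trees = [
            parse_newick(caterpillar("(X1:1,X2:1)", others[r:] + others[:r]))
            for r in range(8)
        ]
        w = caterpillar(f"({others[0]}:1,{others[1]}:1)", others[2:] + ["X1", "X2"])
        winner = parse_newick(w)
        sample = TreeSample(trees=x_trees + [winner, winner.copy()], burnin_fraction=0.0)
        table = build_clade_table(sample)
        assert table.pp(frozenset(("X1", "X2"))) == pytest.approx(0.8)
        cons = mcc_tree(sample, table)
        assert extract_clades(cons.tree) == extract_clades(winner)
        report = unrepresented_clades(table, cons, criterion="above_half")
        missing = {c for c, _ in report.clades}
        assert frozenset(("X1", "X2")) in missing
        assert report.max_pp == pytest.approx(0.8)

    def test_criterion_nesting_min_supersets_mean(self, serial_tree):
        sample = perturbation_sample(serial_tree, n_trees=40, diffusion=4.0, seed=5)
        table = build_clade_table(sample)
        cons = mcc_tree(sample, table)
        by_min = unrepresented_clades(table, cons, criterion="above_min_pp")
        by_mean = unrepresented_clades(table, cons, criterion="above_mean_pp")
        assert {c for c, _ in by_mean.clades} <= {c for c, _ in by_min.clades}
        assert by_min.max_pp >= by_mean.max_pp

    def test_reported_pps_satisfy_criterion(self, serial_tree):
        sample = perturbation_sample(serial_tree, n_trees=40, diffusion=4.0, seed=6)
        table = build_clade_table(sample)
        cons = map_tree(sample)
        report = unrepresented_clades(table, cons, criterion="above_half")
        target = extract_clades(cons.tree)
        for clade, pp in report.clades:
            assert pp > 0.5
            assert clade not in target

    def test_unknown_criterion_rejected(self, serial_tree):
        sample = perturbation_sample(serial_tree, n_trees=5, diffusion=0.0, seed=0)
        table = build_clade_table(sample)
        with pytest.raises(ValueError):
            unrepresented_clades(table, mrc_tree(table), criterion="bogus")


class TestRunExperiment:
    def test_smoke_two_replicates(self):
        cfg = ExperimentConfig(
            n_replicates=2,
            character_counts=(10,),
            simulation=SimulationConfig(n_extant=5, n_fossil=1, seed=0),
            mcmc=McmcConfig(n_generations=400, sample_every=20, seed=0),
            seed=3,
        )
        result = run_experiment(cfg)
        assert not result.failures
        df = result.per_replicate
        assert set(df.method) == {"MCC-sum", "MCC-product", "MAP", "MRC"}
        assert len(df) == 2 * 4
        # conservation and bounds on every row
        assert (df.n_correct + df.n_incorrect == df.n_clades).all()
        assert (df.n_resolved <= df.max_resolved).all()
        assert (df.score.abs() <= df.n_clades).all()
        assert result.diffusion_table().shape[0] == 1
        assert {"mean_incorrect", "mean_pct_incorrect"} <= set(result.accuracy_table().columns)

    def test_deterministic_given_seed(self):
        cfg = dict(
            n_replicates=1, character_counts=(10,),
            simulation=SimulationConfig(n_extant=5, n_fossil=1),
            mcmc=McmcConfig(n_generations=200, sample_every=20),
            seed=5,
        )
        r1 = run_experiment(ExperimentConfig(**cfg))
        r2 = run_experiment(ExperimentConfig(**cfg))
        assert r1.per_replicate.equals(r2.per_replicate)
        assert r1.truth_tree.newick() == r2.truth_tree.newick()

    def test_output_files_written(self, tmp_path):
        cfg = ExperimentConfig(
            n_replicates=1, character_counts=(10,),
            simulation=SimulationConfig(n_extant=5, n_fossil=1),
            mcmc=McmcConfig(n_generations=200, sample_every=20),
            seed=6,
        )
        result = run_experiment(cfg)
        result.write(str(tmp_path / "out"))
        for name in ("per_replicate.tsv", "diffusion.tsv", "accuracy.tsv", "manifest.json"):
            assert (tmp_path / "out" / name).exists()
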