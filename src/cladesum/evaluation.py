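"""Scoring consensus trees against the generating tree, and the replicate
experiment runner.

A consensus clade is *correct* iff its tip set is monophyletic in the
generating tree (exact tip-set equality with some truth clade); otherwise
it is incorrect. The root clade is counted (it is trivially always
correct), which makes the denominator for a fully resolved rooted 36-tip
tree 35. Percentages use the consensus tree's own internal node count, so
a partially resolved MRC tree is judged against its own resolution.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .consensus import CladeTable, ConsensusTree, build_clade_table, map_tree, mcc_tree, mrc_tree
from .mk import McmcConfig, TipDatedMkModel, unique_clade_count
from .simulate import SimulationConfig, simulate_mk_matrix, simulate_serial_tree
from .trees import Tree, extract_clades

__all__ = [
    "AccuracyReport",
    "UnrepresentedCladeReport",
    "ExperimentConfig",
    "ExperimentResult",
    "score_consensus",
    "unrepresented_clades",
    "run_experiment",
]


@dataclass
class AccuracyReport:
    """Clade-accuracy bookkeeping for one consensus tree vs. the truth."""

    method: str
    n_clades: int
    n_correct: int
    n_incorrect: int
    n_resolved: int
    max_resolved: int

    @property
    def pct_correct(self) -> float:
        return 100.0 * self.n_correct / self.n_clades

    @property
    def pct_incorrect(self) -> float:
        return 100.0 * self.n_incorrect / self.n_clades

    @property
    def score(self) -> int:
        """Correct minus incorrect clades: the overall topology-accuracy score."""
        return self.n_correct - self.n_incorrect

    def as_dict(self) -> dict:
        d = asdict(self)
        d.update(pct_correct=self.pct_correct, pct_incorrect=self.pct_incorrect,
                 score=self.score)
        return d


def score_consensus(consensus: ConsensusTree | Tree, truth: Tree,
                    method: str | None = None) -> AccuracyReport:
    """Count correct and incorrect clades of a consensus tree.

    Every clade of the consensus tree (root included, whether defined by a
    bifurcation or a polytomy) is compared by exact tip-set equality with
    the truth tree's clades. Polytomies are not themselves penalized; they
    simply contribute fewer clades.
    """
    tree = consensus.tree if isinstance(consensus, ConsensusTree) else consensus
    if method is None:
        method = consensus.method if isinstance(consensus, ConsensusTree) else "tree"
    if tree.tip_set != truth.tip_set:
        raise ValueError("consensus and truth tip sets differ")
    truth_clades = extract_clades(truth)
    cons_clades = extract_clades(tree)
    n_correct = sum(1 for c in cons_clades if c in truth_clades)
    return AccuracyReport(
        method=method,
        n_clades=len(cons_clades),
        n_correct=n_correct,
        n_incorrect=len(cons_clades) - n_correct,
        n_resolved=len(tree.internal_nodes()),
        max_resolved=tree.n_tips - 1,
    )


# ---------------------------------------------------------------------------
# Valid-but-unrepresented clades
# ---------------------------------------------------------------------------

_CRITERIA = ("above_min_pp", "above_mean_pp", "above_half")


@dataclass
class UnrepresentedCladeReport:
    """Sampled clades that meet a support criterion yet are absent from a
    target consensus tree."""

    criterion: str
    clades: list  # (Clade, pp), pp-descending
    max_pp: float
    n_mrc_missing: int

    @property
    def n_clades(self) -> int:
        return len(self.clades)


def unrepresented_clades(table: CladeTable, target: ConsensusTree,
                         criterion: str = "above_half") -> UnrepresentedCladeReport:
    """Find valid-but-unrepresented clades relative to a consensus tree.

    Criteria: ``above_min_pp`` — pp greater than the most poorly supported
    clade in the target tree; ``above_mean_pp`` — pp greater than the mean
    pp of the target's clades; ``above_half`` — pp > 0.5. The root clade
    (pp 1 by construction) is left out of the min/mean statistics. Also
    counts how many MRC clades are missing from the target.
    """
    if criterion not in _CRITERIA:
        raise ValueError(f"criterion must be one of {_CRITERIA}")
    target_clades = target.clades()
    full = target.tree.tip_set
    pps = [table.pp(c) for c in target_clades if c != full]
    if criterion == "above_half":
        threshold = 0.5
    elif criterion == "above_min_pp":
        threshold = min(pps) if pps else 1.0
    else:
        threshold = float(np.mean(pps)) if pps else 1.0
    hits = [(c, pp) for c, pp in table.entries.items()
            if pp > threshold and c not in target_clades]
    hits.sort(key=lambda t: (-t[1], sorted(t[0])))
    mrc = mrc_tree(table)
    n_mrc_missing = sum(1 for c in mrc.clades() if c not in target_clades)
    return UnrepresentedCladeReport(
        criterion=criterion,
        clades=hits,
        max_pp=max((pp for _, pp in hits), default=0.0),
        n_mrc_missing=n_mrc_missing,
    )


# ---------------------------------------------------------------------------
# Replicate experiment
# ---------------------------------------------------------------------------

_METHODS = ("MCC-sum", "MCC-product", "MAP", "MRC")


@dataclass
class ExperimentConfig:
    """One consensus-efficacy experiment: replicate matrices of each size
    simulated on one truth tree, analyzed by MCMC, summarized four ways."""

    n_replicates: int = 10
    character_counts: tuple = (100, 1000)
    truth_tree: Tree | None = None  # generated from `simulation` when None
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    mcmc: McmcConfig = field(default_factory=McmcConfig)
    clock_rate: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if not self.character_counts:
            raise ValueError("character_counts must be nonempty")


@dataclass
class ExperimentResult:
    """Per-replicate records plus the two headline summary tables."""

    per_replicate: pd.DataFrame
    truth_tree: Tree
    config: ExperimentConfig
    failures: list = field(default_factory=list)

    def diffusion_table(self) -> pd.DataFrame:
        """Unique sampled clades per character count (mean and range)."""
        g = (self.per_replicate.drop_duplicates(["characters", "replicate"])
             .groupby("characters")["unique_clades"])
        return pd.DataFrame({"mean": g.mean(), "min": g.min(), "max": g.max()}).reset_index()

    def accuracy_table(self) -> pd.DataFrame:
        """Incorrect clades per method and character count (mean and range,
        absolute and percentage)."""
        g = self.per_replicate.groupby(["characters", "method"])
        out = g.agg(
            mean_incorrect=("n_incorrect", "mean"),
            min_incorrect=("n_incorrect", "min"),
            max_incorrect=("n_incorrect", "max"),
            mean_pct_incorrect=("pct_incorrect", "mean"),
            min_pct_incorrect=("pct_incorrect", "min"),
            max_pct_incorrect=("pct_incorrect", "max"),
            mean_score=("score", "mean"),
            n_replicates=("replicate", "count"),
        ).reset_index()
        return out

    def write(self, outdir: str) -> None:
        import os

        os.makedirs(outdir, exist_ok=True)
        self.per_replicate.to_csv(os.path.join(outdir, "per_replicate.tsv"), sep="\t", index=False)
        self.diffusion_table().to_csv(os.path.join(outdir, "diffusion.tsv"), sep="\t", index=False)
        self.accuracy_table().to_csv(os.path.join(outdir, "accuracy.tsv"), sep="\t", index=False)
        manifest = {
            "seed": self.config.seed,
            "n_replicates": self.config.n_replicates,
            "character_counts": list(self.config.character_counts),
            "clock_rate": self.config.clock_rate,
            "mcmc": {"n_generations": self.config.mcmc.n_generations,
                     "sample_every": self.config.mcmc.sample_every,
                     "n_chains": self.config.mcmc.n_chains,
                     "burnin_fraction": self.config.mcmc.burnin_fraction},
            "truth_tree": self.truth_tree.newick(),
            "failures": self.failures,
        }
        with open(os.path.join(outdir, "manifest.json"), "w") as fh:
            json.dump(manifest, fh, indent=2)


def _replicate_row_base(characters: int, replicate: int, seed: int, uniq: int) -> dict:
    return {"characters": characters, "replicate": replicate, "seed": seed,
            "unique_clades": uniq}


def run_experiment(config: ExperimentConfig, progress: bool = False) -> ExperimentResult:
    """Run the full simulate → infer → summarize → score pipeline.

    For each character count and replicate: a matrix is simulated on the
    truth tree under Mk with a strict clock, the tip-dated MCMC is run, the
    clade table is built, and MCC-sum / MCC-product / MAP / MRC trees are
    scored against the truth tree. Replicate failures are recorded and
    skipped; the summary notes the effective replicate count.
    """
    rng = np.random.default_rng(config.seed)
    truth = config.truth_tree
    if truth is None:
        sim = config.simulation
        truth = simulate_serial_tree(
            SimulationConfig(
                n_extant=sim.n_extant, n_fossil=sim.n_fossil, birth_rate=sim.birth_rate,
                death_rate=sim.death_rate, root_age_target=sim.root_age_target,
                clock_rate=sim.clock_rate, seed=int(rng.integers(2**31 - 1)),
            )
        )
    tip_ages = truth.tip_ages()
    rows: list = []
    failures: list = []
    for characters in config.character_counts:
        for rep in range(config.n_replicates):
            rep_seed = int(rng.integers(2**31 - 1))
            try:
                matrix = simulate_mk_matrix(truth, characters, config.clock_rate, seed=rep_seed)
                model = TipDatedMkModel(matrix, tip_ages=tip_ages)
                res = model.fit(config.mcmc, seed=rep_seed)
                sample = res.tree_sample
                table = build_clade_table(sample)
                uniq = unique_clade_count(sample)
                consensuses = {
                    "MCC-sum": mcc_tree(sample, table, mode="sum"),
                    "MCC-product": mcc_tree(sample, table, mode="product"),
                    "MAP": map_tree(sample),
                    "MRC": mrc_tree(table, tip_ages=tip_ages),
                }
                for name, cons in consensuses.items():
                    report = score_consensus(cons, truth, method=name)
                    row = _replicate_row_base(characters, rep, rep_seed, uniq)
                    row.update(report.as_dict())
                    rows.append(row)
            except Exception as exc:  # pragma: no cover - defensive
                failures.append({"characters": characters, "replicate": rep,
                                 "error": repr(exc)})
            if progress:  # pragma: no cover
                print(f"characters={characters} replicate={rep} done")
    per_replicate = pd.DataFrame(rows)
    return ExperimentResult(per_replicate=per_replicate, truth_tree=truth,
                            config=config, failures=failures)
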