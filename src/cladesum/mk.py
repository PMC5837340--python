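"""Tip-dated strict-clock Bayesian inference under the 2-state Mk model.

The model coestimates a rooted time tree and a strict clock rate from a
binary character matrix, with non-contemporaneous tip ages fixed as
errorless point calibrations. The likelihood is the Felsenstein pruning
algorithm under the symmetric 2-state Markov model (uniform stationary
frequencies); the posterior is explored by Metropolis-Hastings with NNI
topology moves, node-age slides, a root-age slide and a clock-rate
multiplier, with optional Metropolis coupling across heated chains.

Priors: clock rate ~ Gamma(1, 2) (shape, rate; mean 0.5); root age ~
Gamma with mean 1 and standard deviation 0.1 (shape 100, rate 100);
topology uniform over labelled rooted topologies; internal node ages
given the root age follow a recursive-uniform construction (each non-root
internal age uniform between the oldest tip in its subtree and its
parent's age, in preorder), a proper prior whose root-age marginal is
exactly the root calibration.

Usage follows the Model/Results convention::

    model = TipDatedMkModel(matrix, tip_ages={"f1": 0.3})
    res = model.fit(n_generations=50_000, sample_every=100, seed=1)
    res.summary()
    mrc = res.consensus("mrc")
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .simulate import CharacterMatrix
from .trees import Node, Tree, TreeSample, extract_clades, write_tree_sample

__all__ = [
    "McmcConfig",
    "TipDatedMkModel",
    "MkMcmcResults",
    "mk_log_likelihood",
    "run_mcmc",
    "unique_clade_count",
]


# ---------------------------------------------------------------------------
# Likelihood
# ---------------------------------------------------------------------------


def _leaf_partials(matrix: CharacterMatrix) -> dict:
    """One-hot (n_characters, 2) conditional likelihoods per taxon."""
    out = {}
    eye = np.eye(2)
    for i, taxon in enumerate(matrix.taxa):
        out[taxon] = eye[matrix.states[i]]
    return out


def _pruning_log_likelihood(tree: Tree, leaf_partials: dict, clock_rate: float) -> float:
    partials: dict[int, np.ndarray] = {}
    for node in tree.postorder():
        if node.is_leaf:
            try:
                partials[id(node)] = leaf_partials[node.label]
            except KeyError:
                raise ValueError(f"taxon {node.label!r} missing from the matrix") from None
            continue
        acc = None
        for child in node.children:
            t = node.age - child.age
            e = math.exp(-2.0 * clock_rate * t)
            ps, pf = 0.5 + 0.5 * e, 0.5 - 0.5 * e
            contrib = partials[id(child)] @ np.array(((ps, pf), (pf, ps)))
            acc = contrib if acc is None else acc * contrib
        partials[id(node)] = acc
    site_lik = 0.5 * partials[id(tree.root)].sum(axis=1)
    return float(np.log(site_lik).sum())


def mk_log_likelihood(tree: Tree, matrix: CharacterMatrix, clock_rate: float) -> float:
    """Log-likelihood of a binary matrix on a time tree under Mk + strict clock.

    Branch durations times ``clock_rate`` give the expected number of
    changes; the root state frequencies are uniform (1/2, 1/2). Computed by
    the pruning algorithm, summing logs over characters. An empty matrix
    (zero characters) has log-likelihood 0.
    """
    missing = set(matrix.taxa) - tree.tip_set
    if missing:
        raise ValueError(f"matrix taxa absent from tree: {sorted(missing)}")
    extra = tree.tip_set - set(matrix.taxa)
    if extra:
        raise ValueError(f"tree tips absent from matrix: {sorted(extra)}")
    if clock_rate < 0:
        raise ValueError("clock_rate must be >= 0")
    if matrix.n_characters == 0:
        return 0.0
    return _pruning_log_likelihood(tree, _leaf_partials(matrix), clock_rate)


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------


@dataclass
class McmcConfig:
    """MCMC settings.

    Defaults are a scaled-down analogue of a typical tip-dating run:
    200,000 single-chain generations sampled every 100 with a 25% burn-in.
    ``clock_rate_prior`` is (shape, rate) of a gamma; the root-age prior is
    parameterized by its mean and standard deviation. Move weights are
    normalized internally.
    """

    n_generations: int = 200_000
    sample_every: int = 100
    n_chains: int = 1
    burnin_fraction: float = 0.25
    clock_rate_prior: tuple = (1.0, 2.0)
    root_age_prior_mean: float = 1.0
    root_age_prior_sd: float = 0.1
    seed: int = 0
    move_weights: dict = field(
        default_factory=lambda: {"nni": 0.4, "node_age": 0.35, "root_age": 0.15, "clock_rate": 0.1}
    )
    root_slide_window: float = 0.1
    clock_multiplier_lambda: float = 2.5
    heat_delta: float = 0.1

    def __post_init__(self) -> None:
        if self.n_generations % self.sample_every != 0:
            raise ValueError("sample_every must divide n_generations")
        if self.root_slide_window <= 0 or self.clock_multiplier_lambda <= 0:
            raise ValueError("proposal windows must be positive")
        if self.n_chains < 1:
            raise ValueError("n_chains must be >= 1")
        shape, rate = self.clock_rate_prior
        if shape <= 0 or rate <= 0 or self.root_age_prior_sd <= 0 or self.root_age_prior_mean <= 0:
            raise ValueError("priors must be proper (positive parameters)")

    @property
    def root_age_prior(self) -> tuple:
        """(shape, rate) of the root-age gamma prior."""
        mean, sd = self.root_age_prior_mean, self.root_age_prior_sd
        shape = (mean / sd) ** 2
        return shape, shape / mean


def _log_gamma_pdf(x: float, shape: float, rate: float) -> float:
    if x <= 0:
        return -math.inf
    return shape * math.log(rate) - gammaln(shape) + (shape - 1) * math.log(x) - rate * x


# ---------------------------------------------------------------------------
# Chain state
# ---------------------------------------------------------------------------


class _ChainState:
    __slots__ = ("tree", "clock_rate", "log_lik", "log_prior", "beta")

    def __init__(self, tree: Tree, clock_rate: float, beta: float):
        self.tree = tree
        self.clock_rate = clock_rate
        self.log_lik = 0.0
        self.log_prior = 0.0
        self.beta = beta

    @property
    def log_posterior(self) -> float:
        return self.beta * self.log_lik + self.log_prior


def _oldest_tip_below(tree: Tree) -> dict:
    out: dict[int, float] = {}
    for node in tree.postorder():
        if node.is_leaf:
            out[id(node)] = node.age
        else:
            out[id(node)] = max(out[id(c)] for c in node.children)
    return out


def _log_age_prior(tree: Tree, root_prior: tuple) -> float:
    """Root-age gamma times the recursive-uniform internal-age density."""
    oldest = _oldest_tip_below(tree)
    lp = _log_gamma_pdf(tree.root.age, *root_prior)
    for node in tree.preorder():
        if node.is_leaf or node.parent is None:
            continue
        width = node.parent.age - oldest[id(node)]
        if width <= 0 or not (oldest[id(node)] < node.age < node.parent.age):
            return -math.inf
        lp -= math.log(width)
    return lp


def _random_resolved_tree(tips: dict, root_age: float, rng: np.random.Generator) -> Tree:
    """Random rooted binary topology over ``tips`` with valid ages."""
    lineages = [Node(label=name, age=age) for name, age in tips.items()]
    while len(lineages) > 1:
        i, j = rng.choice(len(lineages), size=2, replace=False)
        a, b = lineages[int(i)], lineages[int(j)]
        parent = Node()
        parent.add_child(a)
        parent.add_child(b)
        lineages = [n for n in lineages if n is not a and n is not b]
        lineages.append(parent)
    tree = Tree(lineages[0])
    max_tip = max(tips.values()) if tips else 0.0
    tree.root.age = max(root_age, max_tip * 1.05 + 1e-9)
    from .simulate import redraw_internal_ages

    redraw_internal_ages(tree, rng)
    return tree


# ---------------------------------------------------------------------------
# Model
# ---------------------------------------------------------------------------


class TipDatedMkModel:
    """Bayesian tip-dated strict-clock model for a binary character matrix.

    Parameters
    ----------
    matrix : CharacterMatrix
        Complete binary matrix; one row per tip.
    tip_ages : mapping, optional
        Fixed ages for non-contemporaneous tips (errorless point
        calibrations). Tips absent from the mapping sit at age 0. Tip ages
        never change during sampling.
    """

    def __init__(self, matrix: CharacterMatrix, tip_ages: dict | None = None):
        self.matrix = matrix
        self.tip_ages = {t: 0.0 for t in matrix.taxa}
        if tip_ages:
            unknown = set(tip_ages) - set(matrix.taxa)
            if unknown:
                raise ValueError(f"tip_ages name taxa absent from the matrix: {sorted(unknown)}")
            self.tip_ages.update({k: float(v) for k, v in tip_ages.items()})
        if any(a < 0 for a in self.tip_ages.values()):
            raise ValueError("tip ages must be >= 0")
        self._leaf_partials = _leaf_partials(matrix)

    # -- posterior pieces --------------------------------------------------

    def _log_lik(self, tree: Tree, clock_rate: float) -> float:
        if self.matrix.n_characters == 0:
            return 0.0
        return _pruning_log_likelihood(tree, self._leaf_partials, clock_rate)

    def _log_prior(self, tree: Tree, clock_rate: float, config: McmcConfig) -> float:
        return _log_age_prior(tree, config.root_age_prior) + _log_gamma_pdf(
            clock_rate, *config.clock_rate_prior
        )

    # -- fitting -----------------------------------------------------------

    def fit(self, config: McmcConfig | None = None, **overrides) -> "MkMcmcResults":
        """Run the MCMC and return an :class:`MkMcmcResults`.

        Keyword overrides (e.g. ``n_generations=5000, seed=3``) are applied
        on top of ``config`` (or the defaults). Deterministic given the
        seed.
        """
        if config is None:
            config = McmcConfig(**overrides)
        elif overrides:
            from dataclasses import replace

            config = replace(config, **overrides)
        rng = np.random.default_rng(config.seed)

        chains = []
        for i in range(config.n_chains):
            beta = 1.0 / (1.0 + config.heat_delta * i)
            root0 = max(config.root_age_prior_mean, max(self.tip_ages.values()) * 1.05 + 1e-9)
            tree = _random_resolved_tree(self.tip_ages, root0, rng)
            clock = float(rng.gamma(config.clock_rate_prior[0], 1.0 / config.clock_rate_prior[1]))
            state = _ChainState(tree, max(clock, 1e-6), beta)
            state.log_lik = self._log_lik(state.tree, state.clock_rate)
            state.log_prior = self._log_prior(state.tree, state.clock_rate, config)
            chains.append(state)

        move_names = list(config.move_weights)
        weights = np.array([config.move_weights[m] for m in move_names], dtype=float)
        weights /= weights.sum()
        attempts = {m: 0 for m in move_names}
        accepts = {m: 0 for m in move_names}
        swap_attempts = swap_accepts = 0

        sampled_trees: list = []
        trace_rows: list = []
        for gen in range(1, config.n_generations + 1):
            for state in chains:
                move = move_names[int(rng.choice(len(move_names), p=weights))]
                attempts[move] += 1
                accepts[move] += self._step(state, move, config, rng)
            if config.n_chains > 1:
                i = int(rng.integers(config.n_chains - 1))
                a, b = chains[i], chains[i + 1]
                swap_attempts += 1
                log_r = (a.beta - b.beta) * (b.log_lik - a.log_lik)
                if math.log(rng.random()) < log_r:
                    a.tree, b.tree = b.tree, a.tree
                    a.clock_rate, b.clock_rate = b.clock_rate, a.clock_rate
                    a.log_lik, b.log_lik = b.log_lik, a.log_lik
                    a.log_prior, b.log_prior = b.log_prior, a.log_prior
                    swap_accepts += 1
            if gen % config.sample_every == 0:
                cold = chains[0]
                sampled_trees.append(cold.tree.copy())
                trace_rows.append(
                    (gen, cold.log_lik, cold.log_prior, cold.clock_rate, cold.tree.root.age)
                )

        trace = pd.DataFrame(
            trace_rows,
            columns=["generation", "log_likelihood", "log_prior", "clock_rate", "root_age"],
        )
        acceptance = {
            m: (accepts[m] / attempts[m] if attempts[m] else math.nan) for m in move_names
        }
        if config.n_chains > 1:
            acceptance["chain_swap"] = swap_accepts / max(swap_attempts, 1)
        sample = TreeSample(trees=sampled_trees, burnin_fraction=config.burnin_fraction)
        return MkMcmcResults(model=self, config=config, tree_sample=sample, trace=trace,
                             acceptance_rates=acceptance)

    # -- proposals ---------------------------------------------------------

    def _step(self, state: _ChainState, move: str, config: McmcConfig,
              rng: np.random.Generator) -> bool:
        tree = state.tree
        if move == "clock_rate":
            lam = config.clock_multiplier_lambda
            factor = math.exp(lam * (rng.random() - 0.5))
            new_rate = state.clock_rate * factor
            new_lik = self._log_lik(tree, new_rate)
            new_prior = self._log_prior(tree, new_rate, config)
            log_r = (state.beta * (new_lik - state.log_lik)
                     + new_prior - state.log_prior + math.log(factor))
            if math.log(rng.random()) < log_r:
                state.clock_rate, state.log_lik, state.log_prior = new_rate, new_lik, new_prior
                return True
            return False

        if move == "root_age":
            old_age = tree.root.age
            new_age = old_age + config.root_slide_window * (2.0 * rng.random() - 1.0)
            if new_age <= max(c.age for c in tree.root.children):
                return False
            tree.root.age = new_age
            return self._metropolis_topology(state, config, rng, log_hastings=0.0,
                                             restore=lambda: setattr(tree.root, "age", old_age))

        if move == "node_age":
            internals = [n for n in tree.internal_nodes() if n.parent is not None]
            if not internals:
                return False
            node = internals[int(rng.integers(len(internals)))]
            lo = max(c.age for c in node.children)
            hi = node.parent.age
            if hi <= lo:
                return False
            old_age = node.age
            node.age = lo + (hi - lo) * rng.random()
            return self._metropolis_topology(state, config, rng, log_hastings=0.0,
                                             restore=lambda: setattr(node, "age", old_age))

        # NNI: swap a random child of an internal non-root node with its sibling,
        # then redraw that node's age uniformly in its new valid window.
        candidates = [n for n in tree.internal_nodes() if n.parent is not None]
        if not candidates:
            return False
        v = candidates[int(rng.integers(len(candidates)))]
        p = v.parent
        siblings = [c for c in p.children if c is not v]
        s = siblings[int(rng.integers(len(siblings)))]
        c = v.children[int(rng.integers(len(v.children)))]
        old_lo = max(ch.age for ch in v.children)
        old_age = v.age
        # swap
        p.children[p.children.index(s)] = c
        v.children[v.children.index(c)] = s
        c.parent, s.parent = p, v
        new_lo = max(ch.age for ch in v.children)
        new_w = p.age - new_lo
        old_w = p.age - old_lo
        if new_w <= 0:
            # no valid age for v under the new topology; undo
            p.children[p.children.index(c)] = s
            v.children[v.children.index(s)] = c
            s.parent, c.parent = p, v
            return False
        v.age = new_lo + new_w * rng.random()

        def restore() -> None:
            p.children[p.children.index(c)] = s
            v.children[v.children.index(s)] = c
            s.parent, c.parent = p, v
            v.age = old_age

        return self._metropolis_topology(state, config, rng,
                                         log_hastings=math.log(new_w) - math.log(old_w),
                                         restore=restore)

    def _metropolis_topology(self, state: _ChainState, config: McmcConfig,
                             rng: np.random.Generator, log_hastings: float,
                             restore) -> bool:
        new_prior = self._log_prior(state.tree, state.clock_rate, config)
        if new_prior == -math.inf:
            restore()
            return False
        new_lik = self._log_lik(state.tree, state.clock_rate)
        log_r = (state.beta * (new_lik - state.log_lik)
                 + new_prior - state.log_prior + log_hastings)
        if math.log(rng.random()) < log_r:
            state.log_lik, state.log_prior = new_lik, new_prior
            return True
        restore()
        return False


# ---------------------------------------------------------------------------
# Results
# ---------------------------------------------------------------------------


@dataclass
class MkMcmcResults:
    """Posterior sample and traces from :meth:`TipDatedMkModel.fit`."""

    model: TipDatedMkModel
    config: McmcConfig
    tree_sample: TreeSample
    trace: pd.DataFrame
    acceptance_rates: dict

    @property
    def post_burnin_trace(self) -> pd.DataFrame:
        return self.trace.iloc[self.tree_sample.n_burnin:]

    def unique_clade_count(self) -> int:
        return unique_clade_count(self.tree_sample)

    def consensus(self, method: str = "mrc", annotate: bool = True):
        """Build a consensus tree (``mrc``, ``mcc-sum``, ``mcc-product``, ``map``)."""
        from . import consensus as _c

        table = _c.build_clade_table(self.tree_sample)
        if method == "mrc":
            cons = _c.mrc_tree(table)
        elif method in ("mcc-sum", "mcc-product"):
            cons = _c.mcc_tree(self.tree_sample, table, mode=method.split("-")[1])
        elif method == "map":
            cons = _c.map_tree(self.tree_sample)
        else:
            raise ValueError(f"unknown consensus method {method!r}")
        if annotate:
            cons = _c.annotate_ages(cons, self.tree_sample)
        return cons

    def summary(self) -> str:
        tr = self.post_burnin_trace
        lines = [
            "Tip-dated strict-clock Mk MCMC",
            "=" * 34,
            f"taxa: {len(self.model.matrix.taxa)}   characters: {self.model.matrix.n_characters}",
            f"generations: {self.config.n_generations}   sampled trees: {len(self.tree_sample)}"
            f"   burn-in: {self.tree_sample.n_burnin}",
            f"unique sampled clades (post burn-in): {self.unique_clade_count()}",
            "",
            "posterior means (post burn-in):",
            f"  clock rate: {tr.clock_rate.mean():.4f}  (sd {tr.clock_rate.std():.4f})",
            f"  root age:   {tr.root_age.mean():.4f}  (sd {tr.root_age.std():.4f})",
            f"  log L:      {tr.log_likelihood.mean():.2f}",
            "",
            "acceptance rates: "
            + "  ".join(f"{k}={v:.2f}" for k, v in self.acceptance_rates.items()),
        ]
        return "\n".join(lines)

    def write_trees(self, path: str) -> None:
        """Write the sampled trees as a MrBayes-style .t NEXUS file."""
        write_tree_sample(self.tree_sample, path)

    def write_trace(self, path: str) -> None:
        """Write the parameter trace as TSV (generation, logL, rate, root age)."""
        self.trace.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Functional surface
# ---------------------------------------------------------------------------


def run_mcmc(matrix: CharacterMatrix, tip_ages: dict | None = None,
             config: McmcConfig | None = None, **overrides) -> TreeSample:
    """Fit :class:`TipDatedMkModel` and return the posterior tree sample."""
    return TipDatedMkModel(matrix, tip_ages).fit(config, **overrides).tree_sample


def unique_clade_count(sample: TreeSample) -> int:
    """Number of unique clades across the post-burn-in trees.

    This is the diffusion proxy: a concentrated posterior visits few
    distinct clades, a diffuse one visits many.
    """
    seen: set = set()
    for tree in sample.post_burnin:
        seen |= extract_clades(tree)
    return len(seen)
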