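"""Synthetic inputs: serially sampled time trees, Mk character matrices,
and perturbation-based surrogate posterior samples.

The study conditions emulated here are a 36-tip time-scaled tree with four
fossil (non-contemporaneous) tips, root age 1, and replicate binary
matrices of 100 / 1,000 / 10,000 characters evolved under the 2-state Mk
model with a strict clock. The tree generator produces statistically
comparable trees from a birth-death process with serially sampled extinct
tips; a user-supplied Newick tree can be substituted anywhere a generated
tree is accepted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .trees import Node, Tree, TreeSample

__all__ = [
    "SimulationConfig",
    "CharacterMatrix",
    "simulate_serial_tree",
    "simulate_mk_matrix",
    "perturbation_sample",
]


@dataclass
class SimulationConfig:
    """Settings for the birth-death tree generator.

    Rates are per-lineage per time unit (pre-rescaling); ``root_age_target``
    fixes the root age of the returned tree, matching the root-calibration
    mean of 1 used in inference. Defaults reproduce the study's 36-tip,
    four-fossil condition.
    """

    n_extant: int = 32
    n_fossil: int = 4
    birth_rate: float = 1.0
    death_rate: float = 0.4
    root_age_target: float = 1.0
    n_characters: int = 100
    clock_rate: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.birth_rate <= 0 or self.death_rate < 0:
            raise ValueError("rates must be positive (death_rate may be 0)")
        if self.n_extant + self.n_fossil < 4:
            raise ValueError("need at least 4 tips in total")
        if self.n_fossil > 0 and self.death_rate == 0:
            raise ValueError("fossil tips require a positive death rate")


@dataclass
class CharacterMatrix:
    """A complete binary character matrix; row order matches ``taxa``."""

    taxa: list
    states: np.ndarray  # (n_taxa, n_characters) over {0, 1}

    def __post_init__(self) -> None:
        self.states = np.asarray(self.states, dtype=np.int8)
        if self.states.ndim != 2 or self.states.shape[0] != len(self.taxa):
            raise ValueError("states must be a (n_taxa, n_characters) grid")
        if self.states.size and not np.isin(self.states, (0, 1)).all():
            raise ValueError("states must be binary")

    @property
    def n_characters(self) -> int:
        return self.states.shape[1]

    def row(self, taxon: str) -> np.ndarray:
        return self.states[self.taxa.index(taxon)]


# ---------------------------------------------------------------------------
# Birth-death tree with serially sampled fossil tips
# ---------------------------------------------------------------------------


def _attempt_bd_tree(config: SimulationConfig, rng: np.random.Generator):
    """One forward Gillespie simulation; returns (root, extant, dead) or None."""
    root = Node(age=0.0)  # ages temporarily hold forward time from the root
    left, right = Node(), Node()
    root.add_child(left)
    root.add_child(right)
    t = 0.0
    alive = [left, right]
    dead: list = []
    total_rate = config.birth_rate + config.death_rate
    # Cap events so pathological rate choices terminate.
    for _ in range(50 * (config.n_extant + config.n_fossil) + 200):
        t += rng.exponential(1.0 / (total_rate * len(alive)))
        lineage = alive[rng.integers(len(alive))]
        lineage.age = t
        if rng.random() < config.birth_rate / total_rate:
            a, b = Node(), Node()
            lineage.add_child(a)
            lineage.add_child(b)
            alive.remove(lineage)
            alive.extend((a, b))
        else:
            alive.remove(lineage)
            dead.append(lineage)
            if not alive:
                return None
        if len(alive) == config.n_extant:
            if len(dead) < config.n_fossil:
                return None
            for tip in alive:
                tip.age = t
            return root, alive, dead, t
    return None


def _prune_to_sampled(root: Node, keep: set) -> Node:
    """Drop unsampled tips and suppress the resulting unifurcations."""

    def rec(node: Node) -> Node | None:
        if not node.children:
            return node if id(node) in keep else None
        kept = [rec(c) for c in node.children]
        kept = [c for c in kept if c is not None]
        if not kept:
            return None
        if len(kept) == 1:
            return kept[0]
        node.children = []
        for c in kept:
            node.add_child(c)
        return node

    new_root = rec(root)
    assert new_root is not None and new_root.children
    new_root.parent = None
    return new_root


def simulate_serial_tree(config: SimulationConfig) -> Tree:
    """Simulate a rooted binary time tree with extant and fossil tips.

    A birth-death process is run forward from the root until ``n_extant``
    lineages are simultaneously alive; ``n_fossil`` of the extinct lineages
    are retained (uniformly at random) as serially sampled fossil tips and
    the rest are pruned. The tree is rescaled so the root age equals
    ``root_age_target``. Rejection-samples until the tip counts are met.
    """
    rng = np.random.default_rng(config.seed)
    for _ in range(1000):
        result = _attempt_bd_tree(config, rng)
        if result is None:
            continue
        root, alive, dead, t_end = result
        fossils = [dead[i] for i in rng.choice(len(dead), size=config.n_fossil, replace=False)]
        keep = {id(n) for n in alive} | {id(n) for n in fossils}
        new_root = _prune_to_sampled(root, keep)
        # forward times -> ages, then rescale root to the target age
        scale = config.root_age_target / (t_end - _forward_time(new_root))
        tree = Tree(new_root)
        for node in tree.preorder():
            node.age = (t_end - node.age) * scale
        for i, leaf in enumerate(tree.leaves()):
            leaf.label = f"t{i + 1}"
        tree.normalize_ages()
        tree.validate()
        return tree
    raise RuntimeError(
        "could not obtain the requested tip counts after 1000 attempts; "
        "adjust birth_rate/death_rate or tip counts"
    )


def _forward_time(node: Node) -> float:
    return node.age


# ---------------------------------------------------------------------------
# Mk character simulation
# ---------------------------------------------------------------------------


def simulate_mk_matrix(
    tree: Tree, n_characters: int, clock_rate: float, seed: int = 0
) -> CharacterMatrix:
    """Evolve independent binary characters down ``tree`` under the Mk model.

    The 2-state Mk process has uniform stationary frequencies; the root
    state is drawn uniformly and the probability of observing the same
    state after a branch of duration t is ``1/2 + 1/2 exp(-2 mu t)`` with
    ``mu`` the strict clock rate. Invariant characters are retained (no
    ascertainment filter).
    """
    if n_characters < 1:
        raise ValueError("n_characters must be >= 1")
    if clock_rate < 0:
        raise ValueError("clock_rate must be >= 0")
    rng = np.random.default_rng(seed)
    states: dict[int, np.ndarray] = {}
    root_state = rng.integers(0, 2, size=n_characters, dtype=np.int8)
    states[id(tree.root)] = root_state
    taxa: list = []
    rows: list = []
    for node in tree.preorder():
        if node.parent is not None:
            t = node.parent.age - node.age
            p_flip = 0.5 - 0.5 * np.exp(-2.0 * clock_rate * t)
            flips = rng.random(n_characters) < p_flip
            states[id(node)] = states[id(node.parent)] ^ flips
        if node.is_leaf:
            taxa.append(node.label)
            rows.append(states[id(node)])
    return CharacterMatrix(taxa=taxa, states=np.array(rows, dtype=np.int8))


# ---------------------------------------------------------------------------
# Surrogate posterior samples via NNI perturbation
# ---------------------------------------------------------------------------


def _eligible_nni_nodes(tree: Tree) -> list:
    return [
        n
        for n in tree.preorder()
        if n.children and n.parent is not None
    ]


def _apply_random_nni(tree: Tree, rng: np.random.Generator) -> None:
    """Swap a random child of a random internal node with that node's sibling."""
    candidates = _eligible_nni_nodes(tree)
    if not candidates:
        return
    v = candidates[rng.integers(len(candidates))]
    p = v.parent
    siblings = [c for c in p.children if c is not v]
    s = siblings[rng.integers(len(siblings))]
    c = v.children[rng.integers(len(v.children))]
    p.children[p.children.index(s)] = c
    v.children[v.children.index(c)] = s
    c.parent, s.parent = p, v


def redraw_internal_ages(tree: Tree, rng: np.random.Generator, root_age: float | None = None) -> None:
    """Re-assign internal node ages top-down, keeping the time tree valid.

    Tip ages are preserved. Each internal node age is drawn uniformly
    between the oldest tip age in its subtree and its parent's age; the
    root age is kept (or set to ``root_age``).
    """
    oldest_below: dict[int, float] = {}
    for node in tree.postorder():
        if node.is_leaf:
            oldest_below[id(node)] = node.age
        else:
            oldest_below[id(node)] = max(oldest_below[id(c)] for c in node.children)
    if root_age is not None:
        tree.root.age = root_age
    tree.root.age = max(tree.root.age, oldest_below[id(tree.root)] * 1.0001 + 1e-12)
    for node in tree.preorder():
        if node.is_leaf or node.parent is None:
            continue
        lo = oldest_below[id(node)]
        hi = node.parent.age
        node.age = lo + (hi - lo) * rng.random()


def perturbation_sample(
    focal: Tree, n_trees: int, diffusion: float, seed: int = 0,
    burnin_fraction: float = 0.0,
) -> TreeSample:
    """Draw a posterior-like tree sample around a focal tree.

    Each draw applies a Poisson(``diffusion``) number of random NNI
    rearrangements to the focal tree, then re-draws internal node ages so
    the result is a valid time tree. ``diffusion`` controls how topologically
    spread-out the sample is, mimicking the diffusion of a posterior sample.
    """
    if diffusion < 0:
        raise ValueError("diffusion must be >= 0")
    rng = np.random.default_rng(seed)
    trees = []
    for _ in range(n_trees):
        tree = focal.copy()
        for _ in range(rng.poisson(diffusion)):
            _apply_random_nni(tree, rng)
        if diffusion > 0:
            redraw_internal_ages(tree, rng)
        trees.append(tree)
    return TreeSample(trees=trees, burnin_fraction=burnin_fraction)
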