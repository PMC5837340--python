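"""MCC, MAP, and MRC consensus trees with clade support and marginal ages.

Three summaries of a posterior tree sample are provided:

* **MCC** (maximum clade credibility): the sampled tree maximizing the sum
  (or product) of the posterior probabilities of its clades.
* **MAP** (maximum a posteriori): the most frequently sampled topology.
* **MRC** (majority-rule consensus): the tree containing exactly the clades
  with posterior probability > 0.5, with unresolved regions left as soft
  polytomies.

Clade posterior probabilities are sample frequencies over the post-burn-in
trees. Marginal clade ages are obtained by collecting, for each consensus
clade, the node age from every sampled tree containing that exact clade;
the mean of that marginal can make a child older than its parent (an
implied negative branch), which is reported, never repaired.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .trees import Clade, Node, Tree, TreeSample, extract_clades, topology_key

__all__ = [
    "CladeTable",
    "ConsensusTree",
    "build_clade_table",
    "mcc_tree",
    "map_tree",
    "mrc_tree",
    "annotate_ages",
    "hpd_interval",
]


@dataclass
class CladeTable:
    """Clade -> posterior probability (sample frequency), post burn-in."""

    entries: dict
    sample_size: int

    def pp(self, clade: Clade) -> float:
        return self.entries.get(clade, 0.0)

    def __len__(self) -> int:
        return len(self.entries)


@dataclass
class ConsensusTree:
    """A consensus tree plus its support and (optional) age annotations.

    ``clade_support`` maps every nontrivial clade of ``tree`` to its
    posterior probability. ``clade_age_summary`` maps each clade to a dict
    with keys ``mean``, ``median``, ``hpd_lower``, ``hpd_upper``, ``n`` once
    :func:`annotate_ages` has run. ``negative_branches`` lists
    (parent_clade, child_clade) pairs whose annotated mean ages imply a
    negative branch length.
    """

    tree: Tree
    clade_support: dict
    method: str
    clade_age_summary: dict | None = None
    negative_branches: list = field(default_factory=list)
    metadata: dict = field(default_factory=dict)

    def clades(self) -> set:
        return extract_clades(self.tree)

    @property
    def n_resolved(self) -> int:
        return len(self.tree.internal_nodes())

    def newick(self, annotated: bool = False, precision: int = 6) -> str:
        if not annotated:
            return self.tree.newick()
        return _annotated_newick(self, precision)


# ---------------------------------------------------------------------------


def build_clade_table(sample: TreeSample) -> CladeTable:
    """Tabulate every nontrivial clade's frequency over the post-burn-in trees."""
    trees = sample.post_burnin
    counts: dict = {}
    for tree in trees:
        for clade in extract_clades(tree):
            counts[clade] = counts.get(clade, 0) + 1
    n = len(trees)
    return CladeTable(entries={c: k / n for c, k in counts.items()}, sample_size=n)


def _credibility(clades: set, table: CladeTable, mode: str) -> float:
    if mode == "sum":
        return sum(table.pp(c) for c in clades)
    if mode == "product":
        return sum(math.log(table.pp(c)) for c in clades)
    raise ValueError(f"unknown MCC mode {mode!r}")


def mcc_tree(sample: TreeSample, table: CladeTable | None = None, mode: str = "sum") -> ConsensusTree:
    """Maximum clade credibility tree of a posterior sample.

    Scores every post-burn-in sampled tree by the sum (``mode='sum'``) or
    log-product (``mode='product'``) of its clades' posterior probabilities
    and returns the best; ties break to the earliest sample index.
    """
    if table is None:
        table = build_clade_table(sample)
    best_idx, best_score = None, -math.inf
    for idx, tree in enumerate(sample.post_burnin):
        score = _credibility(extract_clades(tree), table, mode)
        if score > best_score:
            best_idx, best_score = idx, score
    winner = sample.post_burnin[best_idx].copy()
    support = {c: table.pp(c) for c in extract_clades(winner)}
    return ConsensusTree(
        tree=winner,
        clade_support=support,
        method=f"MCC-{mode}",
        metadata={"score": best_score, "sample_index": best_idx,
                  "tie_break": "earliest sample index"},
    )


def map_tree(sample: TreeSample) -> ConsensusTree:
    """Maximum a posteriori topology, estimated by sampling frequency.

    The topology (clade-set equivalence class) sampled most often wins;
    ties break to the higher MCC-sum credibility, then the earliest index.
    """
    table = build_clade_table(sample)
    counts: dict = {}
    first_idx: dict = {}
    for idx, tree in enumerate(sample.post_burnin):
        key = topology_key(tree)
        counts[key] = counts.get(key, 0) + 1
        first_idx.setdefault(key, idx)
    best_key = max(
        counts,
        key=lambda k: (counts[k], _credibility(set(k), table, "sum"), -first_idx[k]),
    )
    winner = sample.post_burnin[first_idx[best_key]].copy()
    support = {c: table.pp(c) for c in extract_clades(winner)}
    freq = counts[best_key] / len(sample.post_burnin)
    return ConsensusTree(
        tree=winner,
        clade_support=support,
        method="MAP",
        metadata={"topology_frequency": freq, "sample_index": first_idx[best_key],
                  "tie_break": "MCC-sum score, then earliest sample index"},
    )


def _assemble_from_clades(clades: set, tip_ages: dict) -> Tree:
    """Build a (possibly multifurcating) tree from a nested clade set."""
    full = frozenset(tip_ages)
    clades = set(clades) | {full}
    ordered = sorted(clades, key=len, reverse=True)
    nodes = {clade: Node() for clade in ordered}
    for clade in ordered:
        if clade == full:
            continue
        parent = min((c for c in clades if clade < c), key=len)
        nodes[parent].add_child(nodes[clade])
    for tip, age in tip_ages.items():
        parent = min((c for c in clades if tip in c), key=len)
        nodes[parent].add_child(Node(label=tip, age=age))
    tree = Tree(nodes[full])
    # provisional valid ages; annotate_ages replaces them with marginal means
    for node in tree.postorder():
        if not node.is_leaf:
            node.age = max(c.age for c in node.children) + 1.0
    return tree


def mrc_tree(table: CladeTable, tip_ages: dict | None = None) -> ConsensusTree:
    """Majority-rule consensus: exactly the clades with pp strictly > 0.5.

    Majority clades are mutually compatible, so they nest into a single
    tree; regions without a majority clade remain soft polytomies. A clade
    at pp = 0.5 exactly is excluded.
    """
    if not table.entries:
        raise ValueError("empty clade table")
    majority = {c for c, pp in table.entries.items() if pp > 0.5}
    full = max(table.entries, key=len)
    if tip_ages is None:
        tip_ages = {t: 0.0 for t in full}
    tree = _assemble_from_clades(majority, tip_ages)
    support = {c: table.pp(c) for c in extract_clades(tree)}
    return ConsensusTree(tree=tree, clade_support=support, method="MRC",
                         metadata={"threshold": 0.5, "threshold_strict": True})


# ---------------------------------------------------------------------------
# Marginal clade ages
# ---------------------------------------------------------------------------


def hpd_interval(values, mass: float = 0.95) -> tuple:
    """Shortest interval containing at least ``mass`` of the sampled values."""
    vals = np.sort(np.asarray(values, dtype=float))
    k = len(vals)
    if k == 0:
        raise ValueError("no values")
    m = int(math.ceil(mass * k))
    m = max(min(m, k), 1)
    widths = vals[m - 1:] - vals[: k - m + 1]
    i = int(np.argmin(widths))
    return float(vals[i]), float(vals[i + m - 1])


def annotate_ages(consensus: ConsensusTree, sample: TreeSample,
                  point_estimate: str = "mean") -> ConsensusTree:
    """Attach marginal age summaries to every clade of a consensus tree.

    For each consensus clade, ages are collected from every post-burn-in
    sampled tree that contains that exact clade (trees lacking the clade
    contribute nothing). Node ages on the returned tree are set to the
    marginal mean (or median); parent/child pairs whose point ages invert
    are recorded in ``negative_branches``.
    """
    if point_estimate not in ("mean", "median"):
        raise ValueError("point_estimate must be 'mean' or 'median'")
    if consensus.tree.tip_set != sample.tip_set:
        raise ValueError("consensus and sample tip sets differ")
    target = consensus.clades()
    ages: dict = {c: [] for c in target}
    for tree in sample.post_burnin:
        for clade, age in tree.clade_ages().items():
            if clade in ages:
                ages[clade].append(age)
    summary: dict = {}
    for clade, vals in ages.items():
        if not vals:  # impossible for MCC/MAP/MRC output, guarded anyway
            summary[clade] = {"mean": math.nan, "median": math.nan,
                              "hpd_lower": math.nan, "hpd_upper": math.nan, "n": 0}
            continue
        lo, hi = hpd_interval(vals)
        summary[clade] = {
            "mean": float(np.mean(vals)),
            "median": float(np.median(vals)),
            "hpd_lower": lo,
            "hpd_upper": hi,
            "n": len(vals),
        }
    annotated = consensus.tree.copy()
    below: dict[int, frozenset] = {}
    for node in annotated.postorder():
        if node.is_leaf:
            below[id(node)] = frozenset((node.label,))
        else:
            members = frozenset().union(*(below[id(c)] for c in node.children))
            below[id(node)] = members
            if members in summary and summary[members]["n"] > 0:
                node.age = summary[members][point_estimate]
    negative = []
    for node in annotated.internal_nodes():
        for child in node.children:
            if child.age > node.age:
                negative.append((below[id(node)], below[id(child)]))
    return ConsensusTree(
        tree=annotated,
        clade_support=dict(consensus.clade_support),
        method=consensus.method,
        clade_age_summary=summary,
        negative_branches=negative,
        metadata={**consensus.metadata, "age_point_estimate": point_estimate},
    )


def _annotated_newick(consensus: ConsensusTree, precision: int = 6) -> str:
    """Newick with square-bracket metadata comments on internal nodes."""
    fmt = f"%.{precision}g"
    tree = consensus.tree
    below: dict[int, frozenset] = {}
    for node in tree.postorder():
        if node.is_leaf:
            below[id(node)] = frozenset((node.label,))
        else:
            below[id(node)] = frozenset().union(*(below[id(c)] for c in node.children))

    def comment(node: Node) -> str:
        clade = below[id(node)]
        if node.is_leaf or clade not in consensus.clade_support:
            return ""
        parts = [f"posterior={fmt % consensus.clade_support[clade]}"]
        if consensus.clade_age_summary and clade in consensus.clade_age_summary:
            s = consensus.clade_age_summary[clade]
            if s["n"] > 0:
                parts.append(f"age_mean={fmt % s['mean']}")
                parts.append("age_95%HPD={" + fmt % s["hpd_lower"] + "," + fmt % s["hpd_upper"] + "}")
        return "[&" + ",".join(parts) + "]"

    def rec(node: Node) -> str:
        if node.is_leaf:
            core = node.label
        else:
            core = "(" + ",".join(rec(c) for c in node.children) + ")" + comment(node)
        if node.parent is None:
            return core
        return core + ":" + (fmt % (node.parent.age - node.age))

    return rec(tree.root) + ";"
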