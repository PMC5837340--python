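"""Rooted time trees, clades, and tree-sample I/O.

The unit of all support and accuracy bookkeeping in this package is the
rooted *clade*: the frozenset of tip labels subtended by an internal node.
Trees are rooted time trees; node ages are measured backwards from the
youngest tip (age 0), so non-contemporaneous (fossil) tips have age > 0 and
branch lengths are durations ``parent_age - child_age``.

Newick and NEXUS parsing is delegated to :mod:`dendropy`; the classes here
are deliberately small so that MCMC proposals and clade extraction stay
cheap.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass
from typing import Iterator

import dendropy

__all__ = [
    "Clade",
    "Node",
    "Tree",
    "TreeSample",
    "TreeParseError",
    "parse_newick",
    "write_newick",
    "read_tree_sample",
    "write_tree_sample",
    "write_nexus_matrix",
    "extract_clades",
    "count_rooted_topologies",
]

#: A clade is an immutable set of tip labels. Singletons are trivial and are
#: never stored in clade tables; the root clade (all tips) is included.
Clade = frozenset


class TreeParseError(ValueError):
    """Raised for malformed Newick/NEXUS input or invalid tip labelling."""


class Node:
    """One node of a rooted tree. Tips carry a label; all nodes carry an age."""

    __slots__ = ("children", "parent", "label", "age")

    def __init__(self, label: str | None = None, age: float = 0.0):
        self.children: list["Node"] = []
        self.parent: "Node | None" = None
        self.label = label
        self.age = age

    def add_child(self, child: "Node") -> "Node":
        child.parent = self
        self.children.append(child)
        return child

    @property
    def is_leaf(self) -> bool:
        return not self.children


class Tree:
    """A rooted time tree with labelled tips and node ages.

    Invariants for a valid time tree: every internal node is older than each
    of its children, and the youngest tip sits at age 0. Consensus annotation
    (mean marginal clade ages) may legitimately violate the first invariant;
    see :func:`cladesum.consensus.annotate_ages`.
    """

    def __init__(self, root: Node):
        self.root = root

    # -- traversal ---------------------------------------------------------

    def preorder(self) -> Iterator[Node]:
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def postorder(self) -> Iterator[Node]:
        out: list[Node] = []
        stack = [self.root]
        while stack:
            node = stack.pop()
            out.append(node)
            stack.extend(node.children)
        return iter(reversed(out))

    def leaves(self) -> list[Node]:
        return [n for n in self.preorder() if n.is_leaf]

    def internal_nodes(self) -> list[Node]:
        return [n for n in self.preorder() if not n.is_leaf]

    @property
    def tips(self) -> list[str]:
        return [n.label for n in self.leaves()]

    @property
    def tip_set(self) -> frozenset:
        return frozenset(self.tips)

    def tip_ages(self) -> dict:
        return {n.label: n.age for n in self.leaves()}

    @property
    def n_tips(self) -> int:
        return len(self.leaves())

    # -- clades ------------------------------------------------------------

    def clades(self) -> set:
        """Nontrivial rooted clades (tip-label sets), root included."""
        return extract_clades(self)

    def clade_ages(self) -> dict:
        """Map each nontrivial clade to the age of the node defining it."""
        out: dict = {}
        below: dict[int, frozenset] = {}
        for node in self.postorder():
            if node.is_leaf:
                below[id(node)] = frozenset((node.label,))
            else:
                members = frozenset().union(*(below[id(c)] for c in node.children))
                below[id(node)] = members
                if len(members) >= 2:
                    out[members] = node.age
        return out

    # -- editing helpers ---------------------------------------------------

    def copy(self) -> "Tree":
        def rec(node: Node) -> Node:
            clone = Node(node.label, node.age)
            for child in node.children:
                clone.add_child(rec(child))
            return clone

        return Tree(rec(self.root))

    def normalize_ages(self) -> None:
        """Shift all ages so that the youngest tip sits at age 0."""
        youngest = min(n.age for n in self.leaves())
        if youngest != 0.0:
            for node in self.preorder():
                node.age -= youngest

    def is_valid_time_tree(self, tol: float = 1e-9) -> bool:
        for node in self.preorder():
            for child in node.children:
                if node.age < child.age - tol:
                    return False
        return True

    def validate(self) -> None:
        labels = self.tips
        if len(labels) != len(set(labels)):
            dupes = sorted({l for l in labels if labels.count(l) > 1})
            raise TreeParseError(f"duplicate tip labels: {', '.join(dupes)}")
        if any(not l for l in labels):
            raise TreeParseError("empty tip label")
        for node in self.internal_nodes():
            if len(node.children) < 2:
                raise TreeParseError("internal node with a single child")

    def newick(self, precision: int = 12) -> str:
        return write_newick(self, precision=precision)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"<Tree {self.n_tips} tips root_age={self.root.age:.4g}>"


@dataclass
class TreeSample:
    """An ordered posterior sample of trees with burn-in metadata.

    ``burnin_fraction`` is the proportion of trees discarded from the start;
    the discarded count is ``floor(burnin_fraction * len(trees))``.
    """

    trees: list
    burnin_fraction: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.burnin_fraction < 1.0:
            raise ValueError("burnin_fraction must lie in [0, 1)")
        if not self.trees:
            raise ValueError("empty tree sample")
        tip_sets = {t.tip_set for t in self.trees}
        if len(tip_sets) != 1:
            raise ValueError("trees in a sample must share one tip label set")

    @property
    def n_burnin(self) -> int:
        return math.floor(self.burnin_fraction * len(self.trees))

    @property
    def post_burnin(self) -> list:
        trees = self.trees[self.n_burnin:]
        if not trees:
            raise ValueError("burn-in discards the entire sample")
        return trees

    @property
    def tip_set(self) -> frozenset:
        return self.trees[0].tip_set

    def __len__(self) -> int:
        return len(self.trees)


# ---------------------------------------------------------------------------
# Newick / NEXUS I/O (dendropy-backed)
# ---------------------------------------------------------------------------


def _from_dendropy(dnode, depth: float, nodes: list) -> Node:
    label = None
    if dnode.is_leaf():
        label = dnode.taxon.label if dnode.taxon is not None else dnode.label
        if label is None:
            raise TreeParseError("leaf without a label")
    node = Node(label=label, age=depth)  # age temporarily holds root-to-node depth
    nodes.append(node)
    for dchild in dnode.child_nodes():
        length = dchild.edge.length
        child = _from_dendropy(dchild, depth + (0.0 if length is None else float(length)), nodes)
        node.add_child(child)
    return node


def _tree_from_dendropy(dtree: dendropy.Tree) -> Tree:
    nodes: list = []
    root = _from_dendropy(dtree.seed_node, 0.0, nodes)
    max_depth = max(n.age for n in nodes if n.is_leaf)
    for n in nodes:
        n.age = max_depth - n.age  # youngest tip defines age 0
    tree = Tree(root)
    tree.validate()
    return tree


def parse_newick(text: str) -> Tree:
    """Parse a rooted Newick string with branch lengths into a time tree.

    Node ages are reconstructed from root-to-tip path lengths: the deepest
    tip defines age 0 and the root age equals the longest root-to-tip path.
    """
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            rooting="force-rooted",
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises several DataError subclasses
        raise TreeParseError(f"malformed Newick: {exc}") from exc
    return _tree_from_dendropy(dtree)


def write_newick(tree: Tree, precision: int = 12) -> str:
    fmt = f"%.{precision}g"

    def rec(node: Node) -> str:
        if node.is_leaf:
            core = node.label
        else:
            core = "(" + ",".join(rec(c) for c in node.children) + ")"
        if node.parent is None:
            return core
        return core + ":" + (fmt % max(node.parent.age - node.age, 0.0))

    return rec(tree.root) + ";"


_TRANSLATE_RE = re.compile(r"\btranslate\b(.*?);", re.IGNORECASE | re.DOTALL)


def read_tree_sample(path: str, burnin_fraction: float = 0.25) -> TreeSample:
    """Read a NEXUS trees file (MrBayes ``.t`` dialect) into a :class:`TreeSample`.

    A Translate block, when present, is resolved to tip labels; trees keep
    file order. ``burnin_fraction`` of the trees (floored) are flagged for
    discard by downstream consumers.
    """
    try:
        dtrees = dendropy.TreeList.get(path=path, schema="nexus", rooting="force-rooted")
    except Exception as exc:
        raise TreeParseError(f"cannot parse NEXUS trees file {path!r}: {exc}") from exc
    if len(dtrees) == 0:
        raise TreeParseError(f"no trees found in {path!r}")
    with open(path) as fh:
        text = fh.read()
    m = _TRANSLATE_RE.search(text)
    declared: set | None = None
    if m:
        declared = set()
        for entry in m.group(1).split(","):
            parts = entry.split()
            if len(parts) >= 2:
                declared.add(parts[1].strip().strip("'\""))
    trees = []
    for dtree in dtrees:
        tree = _tree_from_dendropy(dtree)
        if declared is not None:
            extra = tree.tip_set - declared
            if extra:
                raise TreeParseError(
                    f"tree cites labels absent from the Translate table: {sorted(extra)}"
                )
        trees.append(tree)
    return TreeSample(trees=trees, burnin_fraction=burnin_fraction)


def write_tree_sample(sample: TreeSample, path: str, precision: int = 12) -> None:
    """Write a MrBayes-style ``.t`` NEXUS file with a Translate block."""
    taxa = sorted(sample.tip_set)
    index = {label: i + 1 for i, label in enumerate(taxa)}
    lines = ["#NEXUS", "", "begin trees;", "\ttranslate"]
    for i, label in enumerate(taxa):
        sep = "," if i < len(taxa) - 1 else ";"
        lines.append(f"\t\t{i + 1} {label}{sep}")
    for gen, tree in enumerate(sample.trees):
        relabeled = tree.copy()
        for leaf in relabeled.leaves():
            leaf.label = str(index[leaf.label])
        lines.append(f"\ttree gen.{gen} = [&R] {relabeled.newick(precision=precision)}")
    lines.append("end;")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def write_nexus_matrix(taxa: list, states, path: str) -> None:
    """Write a binary character matrix as a NEXUS data block (symbols "01")."""
    states = [[int(s) for s in row] for row in states]
    nchar = len(states[0]) if states else 0
    width = max(len(t) for t in taxa) + 2
    lines = [
        "#NEXUS",
        "",
        "begin data;",
        f"\tdimensions ntax={len(taxa)} nchar={nchar};",
        '\tformat datatype=standard symbols="01" missing=? gap=-;',
        "\tmatrix",
    ]
    for label, row in zip(taxa, states):
        lines.append("\t\t" + label.ljust(width) + "".join(str(s) for s in row))
    lines.extend(["\t;", "end;"])
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Clade extraction and topology counting
# ---------------------------------------------------------------------------


def extract_clades(tree: Tree) -> set:
    """All nontrivial rooted clades of ``tree`` (one per internal node).

    The root clade (all tips) is included; singletons are excluded. For a
    fully resolved rooted tree of n tips this yields exactly n - 1 clades
    (35 for a 36-tip tree).
    """
    return set(tree.clade_ages().keys())


def topology_key(tree: Tree) -> frozenset:
    """A hashable identifier of the rooted topology: its clade set."""
    return frozenset(extract_clades(tree))


def count_rooted_topologies(n: int) -> int:
    """Number of labelled, rooted, strictly bifurcating topologies on n taxa.

    Equals (2n - 3)! / (2^(n-2) (n - 2)!), i.e. the double factorial
    (2n - 3)!!, computed exactly.
    """
    if n < 2:
        raise ValueError("need at least 2 taxa")
    return math.prod(range(1, 2 * n - 2, 2))
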