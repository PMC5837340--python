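"""Independent brute-force oracles used by the test suite.

Everything here is deliberately naive — exhaustive enumeration, direct
summation, event-level simulation — and shares no code with the package
implementations it checks.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


# ---------------------------------------------------------------------------
# Rooted-topology enumeration (nested-tuple representation)
# ---------------------------------------------------------------------------


def _attachment_points(tree):
    """Yield (path, subtree) for every node of a nested-tuple tree."""
    yield (), tree
    if isinstance(tree, tuple):
        for i, child in enumerate(tree):
            for path, sub in _attachment_points(child):
                yield (i,) + path, sub


def _replace(tree, path, new_subtree):
    if not path:
        return new_subtree
    i = path[0]
    return tuple(_replace(c, path[1:], new_subtree) if j == i else c
                 for j, c in enumerate(tree))


def enumerate_rooted_topologies(labels):
    """All labelled rooted binary topologies, by leaf addition."""
    labels = list(labels)
    trees = [labels[0]]
    for leaf in labels[1:]:
        nxt = []
        for tree in trees:
            for path, sub in _attachment_points(tree):
                nxt.append(_replace(tree, path, (sub, leaf)))
        trees = nxt
    return trees


def tuple_tree_clades(tree):
    """Nontrivial clades (frozensets of labels) of a nested-tuple tree."""
    clades = set()

    def rec(node):
        if not isinstance(node, tuple):
            return frozenset((node,))
        members = frozenset().union(*(rec(c) for c in node))
        if len(members) >= 2:
            clades.add(members)
        return members

    rec(tree)
    return clades


# ---------------------------------------------------------------------------
# Mk likelihood by exhaustive summation over internal states
# ---------------------------------------------------------------------------


def _p_same(mu, t):
    return 0.5 + 0.5 * math.exp(-2.0 * mu * t)


def brute_force_mk_log_likelihood(tree, matrix, clock_rate):
    """Sum over all internal-node state assignments (2-state Mk).

    ``tree`` is a cladesum Tree; only its node structure and ages are read.
    """
    internals = [n for n in tree.preorder() if not n.is_leaf]
    leaves = tree.leaves()
    row = {t: matrix.states[matrix.taxa.index(t)] for t in matrix.taxa}
    total = 0.0
    for char in range(matrix.n_characters):
        leaf_state = {id(n): int(row[n.label][char]) for n in leaves}
        prob = 0.0
        for assignment in itertools.product((0, 1), repeat=len(internals)):
            states = dict(leaf_state)
            for node, s in zip(internals, assignment):
                states[id(node)] = s
            p = 0.5  # uniform root state frequency
            for node in internals:
                for child in node.children:
                    t = node.age - child.age
                    same = _p_same(clock_rate, t)
                    p *= same if states[id(node)] == states[id(child)] else 1.0 - same
            prob += p
        total += math.log(prob)
    return total


def event_level_two_tip_identity_fraction(mu, t, n_characters, seed):
    """Fraction of characters identical at the two ends of a path of
    duration ``t``, simulated at the substitution-event level (each event
    flips the state; events arrive at rate ``mu``)."""
    rng = np.random.default_rng(seed)
    flips = rng.poisson(mu * t, size=n_characters)
    return float(np.mean(flips % 2 == 0))


# ---------------------------------------------------------------------------
# Consensus oracles
# ---------------------------------------------------------------------------


def brute_force_mcc(trees, clade_pp, mode):
    """(index, score) of the best tree by exhaustive rescoring.

    ``trees`` are cladesum Trees (post burn-in); ``clade_pp`` maps clade ->
    posterior probability.
    """
    from cladesum.trees import extract_clades

    best_idx, best = None, -math.inf
    for i, tree in enumerate(trees):
        clades = extract_clades(tree)
        if mode == "sum":
            score = sum(clade_pp[c] for c in clades)
        else:
            score = sum(math.log(clade_pp[c]) for c in clades)
        if score > best:
            best_idx, best = i, score
    return best_idx, best


def brute_force_topology_frequencies(trees):
    """Map topology (frozenset of clades) -> sampled frequency."""
    from cladesum.trees import extract_clades

    counts = {}
    for tree in trees:
        key = frozenset(extract_clades(tree))
        counts[key] = counts.get(key, 0) + 1
    n = len(trees)
    return {k: v / n for k, v in counts.items()}


def brute_force_hpd(values, mass=0.95):
    """Shortest interval over all index windows containing >= mass."""
    vals = sorted(values)
    k = len(vals)
    need = math.ceil(mass * k)
    best = None
    for i in range(k):
        for j in range(i, k):
            if j - i + 1 >= need:
                width = vals[j] - vals[i]
                if best is None or width < best[0]:
                    best = (width, vals[i], vals[j])
                break
    return best[1], best[2]


def brute_force_accuracy(consensus_clades, truth_clades):
    """(n_correct, n_incorrect) by direct set membership tests."""
    correct = sum(1 for c in consensus_clades if c in truth_clades)
    return correct, len(consensus_clades) - correct
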