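"""Independent brute-force oracles used by the test suite.

These are written against the definitions, not the package internals:
dendropy supplies tree surgery and path sums, and the quartet arithmetic is
spelled out directly in terms of pair sums.
"""

from __future__ import annotations

import itertools

import dendropy
import numpy as np


def dendropy_patristic(newick: str, leaf_order) -> np.ndarray:
    """All-pairs patristic distances via dendropy's distance matrix."""
    tree = dendropy.Tree.get(data=newick, schema="newick",
                             preserve_underscores=True)
    pdm = tree.phylogenetic_distance_matrix()
    taxa = {t.label: t for t in tree.taxon_namespace}
    n = len(leaf_order)
    out = np.zeros((n, n))
    for i, a in enumerate(leaf_order):
        for j, b in enumerate(leaf_order):
            if i != j:
                out[i, j] = pdm.patristic_distance(taxa[a], taxa[b])
    return out


def restricted_split(newick: str, four_labels) -> frozenset:
    """Quartet topology by tree restriction: prune to the four taxa and read
    off which pair shares a cherry.  Returns a frozenset of the two paired
    label-frozensets, e.g. {{A,B},{C,D}}."""
    tree = dendropy.Tree.get(data=newick, schema="newick",
                             preserve_underscores=True)
    keep = [t for t in tree.taxon_namespace if t.label in set(four_labels)]
    assert len(keep) == 4
    tree.retain_taxa(keep)
    tree.suppress_unifurcations()
    # in a pruned 4-leaf tree, exactly one pair of leaves shares a parent
    # node on each side of the internal edge
    for leaf in tree.leaf_node_iter():
        siblings = [
            c for c in leaf.parent_node.child_nodes()
            if c.is_leaf() and c is not leaf
        ]
        if siblings:
            pair = frozenset({leaf.taxon.label, siblings[0].taxon.label})
            rest = frozenset(set(four_labels) - pair)
            return frozenset({pair, rest})
    raise AssertionError("no cherry found in restricted quartet tree")


def brute_force_quartet_score(D: np.ndarray, splits) -> float:
    """Quartet score recomputed per 4-subset from pair sums alone.

    A reference split ij|kl counts as correct when its pair sum dominates:
    s_ref + |s_a - s_b| < min(s_a, s_b) for the two alternative pairings,
    which is the |e| < f condition written without e and f.
    """
    good = 0
    for (i, j, k, l) in splits:
        s_ref = D[i, j] + D[k, l]
        s_a = D[i, k] + D[j, l]
        s_b = D[i, l] + D[j, k]
        if s_ref + abs(s_a - s_b) < min(s_a, s_b):
            good += 1
    return good / len(splits)


def all_fourset_splits_from_restriction(newick: str, leaf_order):
    """Induced split for every 4-subset, via the restriction oracle, as
    canonical (i, j, k, l) index tuples."""
    index = {lab: i for i, lab in enumerate(leaf_order)}
    out = []
    for labels in itertools.combinations(leaf_order, 4):
        pairing = restricted_split(newick, labels)
        (p1, p2) = sorted(
            (sorted(index[x] for x in side) for side in pairing)
        )
        out.append((p1[0], p1[1], p2[0], p2[1]))
    return sorted(out)
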