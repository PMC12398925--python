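"""Reference trees: Newick I/O, patristic distances, quartet enumeration.

An unrooted binary tree ``T`` on ``n`` taxa induces, for every edge ``q``, a
bipartition ``L_q | R_q`` of the leaves and hence a set of quartet splits
``{ij|kl : i,j in L_q, k,l in R_q}``.  Every 4-subset of leaves is separated
by exactly one internal path, so after deduplication the full quartet set
contains ``C(n, 4)`` splits — 715 for 13 taxa.  These splits are the training
targets for the quartet loss and the reference against which latent distance
matrices are scored.

Trees are parsed with dendropy; rooted inputs are accepted and treated as
unrooted (a degree-2 root merely subdivides one edge, which changes neither
patristic distances nor induced quartet topologies).  Leaf indices are
assigned by sorted label order and used consistently by every matrix and
table in the package.
"""

from __future__ import annotations

import itertools
from typing import Callable, Optional, Sequence

import dendropy
import numpy as np

from .distances import DistanceMatrix
from .quartets import QuartetTable

__all__ = [
    "NewickParseError",
    "TreeValidationError",
    "ReferenceTree",
    "parse_newick",
    "write_newick",
    "patristic_matrix",
    "enumerate_quartets",
    "shuffle_taxa",
    "random_binary_tree",
]


class NewickParseError(ValueError):
    """Raised when a Newick string cannot be parsed."""


class TreeValidationError(ValueError):
    """Raised when a parsed tree violates the package's requirements."""


class ReferenceTree:
    """A fully resolved reference phylogeny with optional branch lengths.

    Parameters
    ----------
    dtree
        A dendropy tree.  The tree must have >= 4 uniquely labelled leaves
        and be fully resolved: after suppressing a degree-2 root every
        internal node has degree 3.

    Attributes
    ----------
    leaves
        Taxon labels in sorted order; position in this tuple is the taxon
        index used by all distance matrices and quartet tables.
    has_branch_lengths
        True when every edge carries a nonnegative length.
    """

    def __init__(self, dtree: dendropy.Tree):
        self._tree = dtree
        self._validate()
        labels = [leaf.taxon.label for leaf in dtree.leaf_node_iter()]
        self.leaves: tuple[str, ...] = tuple(sorted(labels))
        self.index: dict[str, int] = {lab: i for i, lab in enumerate(self.leaves)}

    # ------------------------------------------------------------------ #
    # validation

    def _validate(self) -> None:
        t = self._tree
        t.suppress_unifurcations()
        seed = t.seed_node
        labels = []
        for node in t.preorder_node_iter():
            nch = len(node.child_nodes())
            if nch == 0:
                if node.taxon is None or not (node.taxon.label or "").strip():
                    raise TreeValidationError("leaf without a label")
                labels.append(node.taxon.label)
            elif node is seed:
                if nch not in (2, 3):
                    raise TreeValidationError(
                        f"polytomy at the root ({nch} children); tree must be "
                        "fully resolved"
                    )
            elif nch != 2:
                raise TreeValidationError(
                    f"polytomy at internal node with {nch} children; tree "
                    "must be fully resolved"
                )
        if len(labels) < 4:
            raise TreeValidationError(
                f"need at least 4 leaves, got {len(labels)}"
            )
        if len(set(labels)) != len(labels):
            dupes = sorted({x for x in labels if labels.count(x) > 1})
            raise TreeValidationError(f"duplicate leaf labels: {dupes}")
        lengths = [
            node.edge.length
            for node in t.preorder_node_iter()
            if node is not seed
        ]
        n_none = sum(1 for x in lengths if x is None)
        if n_none == 0:
            if any(x < 0 for x in lengths):
                raise TreeValidationError("negative branch length")
            self.has_branch_lengths = True
        elif n_none == len(lengths):
            self.has_branch_lengths = False
        else:
            raise TreeValidationError(
                "branch lengths must be given for all edges or none"
            )

    # ------------------------------------------------------------------ #
    # constructors / serialization

    @classmethod
    def from_newick(cls, text: str) -> "ReferenceTree":
        try:
            dtree = dendropy.Tree.get(
                data=text,
                schema="newick",
                preserve_underscores=True,
                suppress_internal_node_taxa=True,
            )
        except Exception as exc:  # dendropy raises several error types
            if "Duplicate taxon" in str(exc):
                raise TreeValidationError(
                    f"duplicate leaf labels: {exc}"
                ) from exc
            raise NewickParseError(f"malformed Newick: {exc}") from exc
        return cls(dtree)

    def to_newick(self) -> str:
        s = self._tree.as_string(
            schema="newick",
            suppress_rooting=True,
            unquoted_underscores=True,
        )
        return s.strip()

    @property
    def n_taxa(self) -> int:
        return len(self.leaves)

    # ------------------------------------------------------------------ #
    # structure access

    def _adjacency(self) -> dict:
        """Unrooted adjacency: node -> list of (neighbour, length).

        A degree-2 seed node is contracted so that the returned graph is the
        unrooted tree; the two root-incident half-edges merge into one edge
        whose length is their sum (None if the tree has no lengths).
        """
        adj: dict = {}
        seed = self._tree.seed_node
        for node in self._tree.preorder_node_iter():
            if node is seed:
                continue
            parent = node.parent_node
            length = node.edge.length
            adj.setdefault(node, []).append((parent, length))
            adj.setdefault(parent, []).append((node, length))
        if len(seed.child_nodes()) == 2:
            c1, c2 = seed.child_nodes()
            l1, l2 = c1.edge.length, c2.edge.length
            merged = None if l1 is None or l2 is None else l1 + l2
            for a, b in ((c1, c2), (c2, c1)):
                adj[a] = [(nb, ln) for nb, ln in adj[a] if nb is not seed]
                adj[a].append((b, merged))
            del adj[seed]
        return adj

    def _leaf_nodes(self) -> dict:
        return {
            leaf.taxon.label: leaf for leaf in self._tree.leaf_node_iter()
        }

    def leaf_path_lengths(self, unit: bool = False) -> np.ndarray:
        """All-pairs leaf-to-leaf path lengths (branch lengths or hop counts)."""
        adj = self._adjacency()
        leaf_nodes = self._leaf_nodes()
        n = self.n_taxa
        out = np.zeros((n, n))
        for label, start in leaf_nodes.items():
            i = self.index[label]
            dist = {start: 0.0}
            stack = [start]
            while stack:
                node = stack.pop()
                for nb, ln in adj[node]:
                    if nb not in dist:
                        w = 1.0 if unit else float(ln)
                        dist[nb] = dist[node] + w
                        stack.append(nb)
            for label2, node2 in leaf_nodes.items():
                out[i, self.index[label2]] = dist[node2]
        return out

    def root_bipartition(self) -> tuple[frozenset, frozenset]:
        """The two leaf sets branching at the displayed root.

        For a degree-2 root these are the leaves below each root child; for a
        trifurcating (already unrooted) seed node, the first child's clade
        versus everything else.
        """
        children = self._tree.seed_node.child_nodes()
        side_a = frozenset(
            leaf.taxon.label for leaf in children[0].leaf_iter()
        )
        side_b = frozenset(self.leaves) - side_a
        if not side_a or not side_b:
            raise TreeValidationError("degenerate root bipartition")
        return side_a, side_b

    def branch_lengths(self) -> list[float]:
        """Multiset of unrooted edge lengths (root half-edges merged)."""
        if not self.has_branch_lengths:
            raise TreeValidationError("tree has no branch lengths")
        adj = self._adjacency()
        seen = set()
        out = []
        for node, nbrs in adj.items():
            for nb, ln in nbrs:
                key = frozenset((id(node), id(nb)))
                if key not in seen:
                    seen.add(key)
                    out.append(float(ln))
        return sorted(out)

    def __repr__(self) -> str:  # pragma: no cover
        return f"ReferenceTree(n_taxa={self.n_taxa}, lengths={self.has_branch_lengths})"


def parse_newick(text: str) -> ReferenceTree:
    """Parse a Newick string into a validated :class:`ReferenceTree`."""
    return ReferenceTree.from_newick(text)


def write_newick(tree: ReferenceTree, path) -> None:
    with open(path, "w") as fh:
        fh.write(tree.to_newick() + "\n")


def patristic_matrix(tree: ReferenceTree) -> DistanceMatrix:
    """Patristic distances: summed branch lengths along each leaf-leaf path.

    The result is an additive tree metric, i.e. it satisfies the four-point
    condition exactly (up to float rounding).
    """
    if not tree.has_branch_lengths:
        raise TreeValidationError(
            "tree has no branch lengths; patristic distances are undefined — "
            "use the topology-only quartet loss/score instead"
        )
    return DistanceMatrix(tree.leaf_path_lengths(unit=False), tree.leaves)


def enumerate_quartets(tree: ReferenceTree) -> QuartetTable:
    """All quartet splits induced by the tree, one per 4-subset of taxa.

    For each 4-subset the tree resolves exactly one of the three pairings:
    the one whose two within-pair paths avoid the internal path separating
    the pairs.  On the hop-count metric of a fully resolved tree that pairing
    is the unique minimizer of the pair-sum, which is how it is found here.
    Splits are stored canonically (i<j, k<l, i<k), in lexicographic order.
    """
    hops = tree.leaf_path_lengths(unit=True)
    n = tree.n_taxa
    rows = []
    for a, b, c, d in itertools.combinations(range(n), 4):
        s_ab = hops[a, b] + hops[c, d]
        s_ac = hops[a, c] + hops[b, d]
        s_ad = hops[a, d] + hops[b, c]
        m = min(s_ab, s_ac, s_ad)
        if s_ab == m:
            rows.append((a, b, c, d))
        elif s_ac == m:
            rows.append((a, c, b, d))
        else:
            rows.append((a, d, b, c))
    return QuartetTable(np.array(rows, dtype=np.int64), n)


def shuffle_taxa(tree: ReferenceTree, seed: int) -> ReferenceTree:
    """Return a copy of the tree with leaf labels uniformly permuted.

    Topology and branch lengths are untouched; only the assignment of taxa
    to leaves changes.  This is the null model for the interpretability
    comparison: a tree with the same shape but scrambled evolutionary
    relationships.
    """
    rng = np.random.default_rng(seed)
    labels = list(tree.leaves)
    perm = rng.permutation(len(labels))
    mapping = {labels[i]: labels[perm[i]] for i in range(len(labels))}
    dtree = dendropy.Tree.get(
        data=tree.to_newick(),
        schema="newick",
        preserve_underscores=True,
        suppress_internal_node_taxa=True,
    )
    for leaf in dtree.leaf_node_iter():
        leaf.taxon.label = mapping[leaf.taxon.label]
    return ReferenceTree(dtree)


def random_binary_tree(
    n: int,
    seed: int,
    length_dist: Optional[Callable[[np.random.Generator], float] | tuple] = None,
    lengths: bool = True,
) -> ReferenceTree:
    """Random fully resolved tree by uniform sequential leaf addition.

    Each new leaf is attached to an edge chosen uniformly among the 2k-3
    edges of the current unrooted tree, which yields the uniform
    addition-order distribution over labelled topologies.  Branch lengths
    default to i.i.d. uniform draws on [0.1, 1.0]; the displayed-root edge's
    draw is split evenly between the two half-edges.

    The displayed root is placed on the edge whose bipartition splits the
    leaves most evenly, mirroring how reference trees of two sister clades
    are usually displayed; the root bipartition is what the simulator's
    evolving segment starts from and what root features are defined
    against.
    """
    if n < 4:
        raise ValueError(f"need n >= 4 taxa, got n={n}")
    rng = np.random.default_rng(seed)
    if length_dist is None:
        draw = lambda r: r.uniform(0.1, 1.0)  # noqa: E731
    elif isinstance(length_dist, tuple):
        lo, hi = length_dist
        draw = lambda r: r.uniform(lo, hi)  # noqa: E731
    else:
        draw = length_dist

    class _N:
        __slots__ = ("parent", "children", "label", "length")

        def __init__(self, label=None):
            self.parent = None
            self.children = []
            self.label = label
            self.length = None

    def _attach(parent, child):
        child.parent = parent
        parent.children.append(child)

    width = max(2, len(str(n)))
    labels = [f"t{i + 1:0{width}d}" for i in range(n)]
    root = _N()
    for lab in labels[:2]:
        _attach(root, _N(lab))
    for k in range(2, n):
        # candidate edges: every non-root node except one root child (the
        # two root half-edges are the same unrooted edge)
        cands = []
        stack = [root]
        while stack:
            node = stack.pop()
            stack.extend(reversed(node.children))
            if node is not root and node is not root.children[1]:
                cands.append(node)
        v = cands[rng.integers(len(cands))]
        u = _N()
        parent = v.parent
        parent.children[parent.children.index(v)] = u
        u.parent = parent
        u.children = [v]
        v.parent = u
        _attach(u, _N(labels[k]))

    def _newick(node) -> str:
        if not node.children:
            return node.label
        return "(" + ",".join(_newick(c) for c in node.children) + ")"

    dtree = dendropy.Tree.get(
        data=_newick(root) + ";",
        schema="newick",
        preserve_underscores=True,
        suppress_internal_node_taxa=True,
    )

    # re-display: root on the edge whose bipartition splits the leaves most
    # evenly (ties broken by traversal order)
    below: dict = {}
    for node in dtree.postorder_node_iter():
        below[node] = 1 if node.is_leaf() else sum(
            below[c] for c in node.child_nodes()
        )
    seed_node = dtree.seed_node
    best, best_imbalance = None, n + 1
    for node in dtree.preorder_node_iter():
        if node is seed_node or node.parent_node is seed_node:
            continue
        imbalance = abs(2 * below[node] - n)
        if imbalance < best_imbalance:
            best, best_imbalance = node, imbalance
    root_children = seed_node.child_nodes()
    current = min(abs(2 * below[c] - n) for c in root_children)
    if best is not None and best_imbalance < current:
        dtree.reroot_at_edge(best.edge, update_bipartitions=False)
        dtree.suppress_unifurcations()

    if lengths:
        seed_node = dtree.seed_node
        for node in dtree.preorder_node_iter():
            if node is not seed_node:
                node.edge.length = draw(rng)
        half = draw(rng) / 2.0
        for child in seed_node.child_nodes()[:2]:
            child.edge.length = half

    return ReferenceTree(dtree)
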