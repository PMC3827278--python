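"""Distance-based tree inference and tree comparison.

Neighbor joining is implemented here in full (Saitou & Nei agglomeration
with the Studier–Keppler Q-criterion) rather than delegated, because the
pipeline's conclusions hinge on reproducible topologies: ties in the
Q-criterion are broken lexicographically on the label pair, negative branch
lengths are clamped to zero with the deficit logged, and the returned
topology is invariant to the input label order.

Tree comparison uses the bipartition (split) view: every internal edge of
an unrooted tree partitions the leaves into two blocks, and the topology
distance between two trees is the size of the symmetric difference of their
non-trivial bipartition sets.  For binary trees this equals twice the
number of internal branches that define different bipartitions, the
Penny–Hendy form of the Robinson–Foulds distance.

Newick reading/writing is delegated to dendropy; the :class:`Tree` wrapper
adds bipartition access, outgroup rooting and patristic distances.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import dendropy
import numpy as np
from skbio import DistanceMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "Bipartition",
    "Tree",
    "parse_newick",
    "write_newick",
    "neighbor_joining",
    "root_with_outgroup",
    "bipartition_set",
    "tree_topology_distance",
]


@dataclass(frozen=True)
class Bipartition:
    """A two-block partition of the leaf set, canonicalized.

    The block containing the lexicographically smallest leaf is listed
    first; blocks are sorted tuples.  Non-trivial iff both blocks have at
    least two leaves.
    """

    first: tuple[str, ...]
    second: tuple[str, ...]

    @classmethod
    def from_blocks(cls, block_a, block_b) -> "Bipartition":
        a = tuple(sorted(block_a))
        b = tuple(sorted(block_b))
        if not a or not b:
            raise ValueError("bipartition blocks must be non-empty")
        if set(a) & set(b):
            raise ValueError("bipartition blocks must be disjoint")
        if a[0] > b[0]:
            a, b = b, a
        return cls(a, b)

    @property
    def nontrivial(self) -> bool:
        return len(self.first) >= 2 and len(self.second) >= 2


class Tree:
    """Leaf-labeled tree with branch lengths, wrapping a dendropy tree."""

    def __init__(self, dtree: dendropy.Tree, rooted: bool = False):
        self._t = dtree
        self._t.is_rooted = rooted
        self.rooted = rooted
        labels = self.leaf_labels
        if len(labels) != len(set(labels)):
            raise ValueError("leaf labels must be unique")

    # -- construction / serialization ------------------------------------
    @classmethod
    def from_newick(cls, s: str, rooted: bool = False) -> "Tree":
        return parse_newick(s, rooted=rooted)

    def to_newick(self) -> str:
        return write_newick(self)

    def copy(self) -> "Tree":
        return Tree(self._t.clone(depth=1), rooted=self.rooted)

    # -- basic accessors --------------------------------------------------
    @property
    def leaf_labels(self) -> list[str]:
        return [leaf.taxon.label for leaf in self._t.leaf_node_iter()]

    @property
    def n_leaves(self) -> int:
        return sum(1 for _ in self._t.leaf_node_iter())

    @property
    def dendropy_tree(self) -> dendropy.Tree:
        return self._t

    # -- bipartitions ------------------------------------------------------
    def bipartitions(self) -> frozenset[Bipartition]:
        """Non-trivial splits, one per internal edge (root placement ignored)."""
        all_leaves = set(self.leaf_labels)
        n = len(all_leaves)
        below: dict[int, set[str]] = {}
        splits: set[Bipartition] = set()
        for node in self._t.postorder_node_iter():
            if node.is_leaf():
                below[id(node)] = {node.taxon.label}
            else:
                below[id(node)] = set().union(*(below[id(c)] for c in node.child_nodes()))
            if node.parent_node is None:
                continue
            side = below[id(node)]
            if 2 <= len(side) <= n - 2:
                splits.add(Bipartition.from_blocks(side, all_leaves - side))
        return frozenset(splits)

    # -- rooting -----------------------------------------------------------
    def root_on_outgroup(self, outgroup_label: str) -> "Tree":
        return root_with_outgroup(self, outgroup_label)

    def sister_group(self, leaf_label: str) -> frozenset[str]:
        """Leaf set of the clade that is sister to ``leaf_label`` (rooted trees)."""
        if not self.rooted:
            raise ValueError("sister_group requires a rooted tree")
        leaf = self._find_leaf(leaf_label)
        parent = leaf.parent_node
        out: set[str] = set()
        for child in parent.child_nodes():
            if child is not leaf:
                out.update(l.taxon.label for l in child.leaf_iter())
        return frozenset(out)

    def _find_leaf(self, label: str) -> dendropy.Node:
        for leaf in self._t.leaf_node_iter():
            if leaf.taxon.label == label:
                return leaf
        raise KeyError(f"no leaf labeled {label!r}")

    def edge_paths_from(self, ref_label: str) -> tuple[list[float], dict[str, list[int]]]:
        """Edges on the path from ``ref_label`` to every leaf.

        Returns (edge_lengths, paths) where ``paths[label]`` lists indices
        into ``edge_lengths`` for the edges on the ref->label path.  Edge
        indexing follows a preorder traversal, so it is deterministic for a
        given tree.
        """
        ref = self._find_leaf(ref_label)
        order: dict[int, int] = {}
        lengths: list[float] = []
        for node in self._t.preorder_node_iter():
            if node.parent_node is None:
                continue
            order[id(node)] = len(lengths)
            lengths.append(float(node.edge.length or 0.0))

        def up_path(node) -> list[int]:
            path = []
            while node.parent_node is not None:
                path.append(order[id(node)])
                node = node.parent_node
            return path

        ref_path = set(up_path(ref))
        paths = {}
        for leaf in self._t.leaf_node_iter():
            leaf_path = set(up_path(leaf))
            paths[leaf.taxon.label] = sorted(ref_path ^ leaf_path)
        return lengths, paths

    # -- distances ---------------------------------------------------------
    def path_distances_from(self, ref_label: str) -> dict[str, float]:
        """Patristic distance from ``ref_label`` to every leaf (0 for itself)."""
        dm = self.distance_matrix()
        return {label: float(dm[ref_label, label]) for label in dm.ids}

    def distance_matrix(self) -> DistanceMatrix:
        """Patristic (path-length) distances between all leaf pairs."""
        labels = sorted(self.leaf_labels)
        pdm = self._t.phylogenetic_distance_matrix()
        taxa = {t.label: t for t in self._t.taxon_namespace if t.label in set(labels)}
        n = len(labels)
        out = np.zeros((n, n))
        for i, a in enumerate(labels):
            for j in range(i + 1, n):
                d = pdm.patristic_distance(taxa[a], taxa[labels[j]])
                out[i, j] = out[j, i] = d
        return DistanceMatrix(out, ids=labels)


def parse_newick(s: str, rooted: bool = False) -> Tree:
    """Parse a newick string; branch lengths are optional and kept absent if missing."""
    try:
        dtree = dendropy.Tree.get(
            data=s, schema="newick", preserve_underscores=True, suppress_internal_node_taxa=True
        )
    except Exception as exc:  # dendropy raises schema-specific subclasses
        raise ValueError(f"malformed newick: {exc}") from exc
    return Tree(dtree, rooted=rooted)


def write_newick(t: Tree) -> str:
    s = t.dendropy_tree.as_string(
        schema="newick", suppress_rooting=True, unquoted_underscores=True
    )
    return s.strip()


def neighbor_joining(m: DistanceMatrix) -> Tree:
    """Saitou–Nei neighbor joining on a labeled distance matrix.

    Joins the pair minimizing Q(i,j) = (n-2) d(i,j) - r_i - r_j; exact ties
    are broken by the lexicographically smallest (sorted) label pair, where
    a cluster is keyed by the smallest leaf label it contains.  Negative
    branch lengths are clamped to 0 (topology untouched) and the total
    clamped deficit is logged.  Returns an unrooted tree.
    """
    labels = list(m.ids)
    n = len(labels)
    if n < 3:
        raise ValueError("neighbor joining requires at least 3 taxa")
    d = np.array(m.data, float)
    if np.isnan(d).any():
        raise ValueError("distance matrix contains NaN")

    taxa = dendropy.TaxonNamespace(sorted(labels))
    nodes = []
    keys = []  # smallest leaf label per active cluster, for tie-breaking
    for label in labels:
        node = dendropy.Node(taxon=taxa.get_taxon(label))
        nodes.append(node)
        keys.append(label)

    clamped = 0.0

    def clamp(v: float) -> float:
        nonlocal clamped
        if v < 0:
            clamped += -v
            return 0.0
        return v

    while len(nodes) > 3:
        k = len(nodes)
        r = d.sum(axis=1)
        best = None
        for i in range(k):
            for j in range(i + 1, k):
                q = (k - 2) * d[i, j] - r[i] - r[j]
                pair_key = tuple(sorted((keys[i], keys[j])))
                cand = (q, pair_key, i, j)
                if best is None or cand[:2] < best[:2]:
                    best = cand
        _, _, i, j = best
        li = 0.5 * d[i, j] + (r[i] - r[j]) / (2.0 * (k - 2))
        lj = d[i, j] - li
        parent = dendropy.Node()
        ni, nj = nodes[i], nodes[j]
        ni.edge.length = clamp(li)
        nj.edge.length = clamp(lj)
        parent.add_child(ni)
        parent.add_child(nj)

        newd = 0.5 * (d[i, :] + d[j, :] - d[i, j])
        keep = [x for x in range(k) if x not in (i, j)]
        d2 = np.zeros((len(keep) + 1, len(keep) + 1))
        d2[:-1, :-1] = d[np.ix_(keep, keep)]
        d2[-1, :-1] = d2[:-1, -1] = newd[keep]
        d = d2
        new_key = min(keys[i], keys[j])
        nodes = [nodes[x] for x in keep] + [parent]
        keys = [keys[x] for x in keep] + [new_key]

    # terminal trifurcation
    la = 0.5 * (d[0, 1] + d[0, 2] - d[1, 2])
    lb = 0.5 * (d[0, 1] + d[1, 2] - d[0, 2])
    lc = 0.5 * (d[0, 2] + d[1, 2] - d[0, 1])
    root = dendropy.Node()
    for node, length in zip(nodes, (la, lb, lc)):
        node.edge.length = clamp(length)
        root.add_child(node)
    if clamped > 0:
        logger.info("neighbor_joining clamped negative branch lengths; total deficit %.6g", clamped)
    dtree = dendropy.Tree(taxon_namespace=taxa, seed_node=root)
    return Tree(dtree, rooted=False)


def root_with_outgroup(t: Tree, outgroup_label: str) -> Tree:
    """Root at the midpoint of the outgroup's pendant edge.

    The set of non-trivial bipartitions is unchanged by rooting.
    """
    out = t.copy()
    dtree = out.dendropy_tree
    leaf = None
    for node in dtree.leaf_node_iter():
        if node.taxon.label == outgroup_label:
            leaf = node
            break
    if leaf is None:
        raise KeyError(f"outgroup {outgroup_label!r} is not a leaf of the tree")
    length = leaf.edge.length
    if length is None:
        dtree.reroot_at_edge(leaf.edge, update_bipartitions=False)
    else:
        dtree.reroot_at_edge(
            leaf.edge, length1=length / 2.0, length2=length / 2.0, update_bipartitions=False
        )
    return Tree(dtree, rooted=True)


def bipartition_set(t: Tree) -> frozenset[Bipartition]:
    """The non-trivial splits of a tree; |set| = n-3 for unrooted binary trees."""
    return t.bipartitions()


def tree_topology_distance(t1: Tree, t2: Tree) -> int:
    """Symmetric-difference (Penny–Hendy / Robinson–Foulds) topology distance.

    Counts splits present in exactly one of the two trees; even for binary
    trees, zero iff identical topologies, at most 2(n-3).
    """
    if set(t1.leaf_labels) != set(t2.leaf_labels):
        raise ValueError("trees must share an identical leaf set")
    b1, b2 = t1.bipartitions(), t2.bipartitions()
    return len(b1 ^ b2)
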