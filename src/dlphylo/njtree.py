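"""Neighbor-joining tree construction, Newick I/O and tree comparison.

The neighbor-joining (Saitou–Nei) algorithm is implemented here in full so
the pipeline is self-contained and deterministic:

* candidate pairs are scored with the Q-criterion
  ``Q_ij = (n − 2)·d_ij − r_i − r_j``;
* ties are broken toward the pair with the lowest (creation-order) indices,
  making the output reproducible;
* estimated branch lengths that come out negative are clamped to zero and
  the deficit is transferred to the sister branch, preserving the path
  length through the new node;
* three remaining nodes are resolved by the closed form
  ``b_A = (d_AB + d_AC − d_BC)/2``.

Trees are carried as :class:`PhyloTree`, a thin wrapper over a dendropy
tree treated as unrooted; Newick serialization is delegated to dendropy.
Bipartition extraction, Robinson–Foulds distance and support annotation are
implemented on top of label sets so they are independent of any particular
rooting or taxon-namespace bookkeeping.
"""

from __future__ import annotations

import dendropy
import numpy as np

from .distance import DistanceMatrix
from .errors import InvalidParameterError, LeafSetMismatchError, NewickFormatError

__all__ = ["PhyloTree", "neighbor_joining", "parse_newick", "robinson_foulds"]

Split = frozenset  # canonical bipartition: the side NOT containing min(label)


class PhyloTree:
    """An unrooted phylogenetic tree with branch lengths and optional supports.

    Wraps a :class:`dendropy.Tree`.  Leaf labels are unique; per-internal-edge
    bootstrap supports, when present, live in ``node.label`` of the child node
    of the edge (the standard Newick convention).
    """

    def __init__(self, tree: dendropy.Tree):
        self._tree = tree
        labels = [lf.taxon.label for lf in tree.leaf_node_iter()]
        if len(set(labels)) != len(labels):
            raise NewickFormatError("duplicate leaf labels in tree")
        if not labels:
            raise NewickFormatError("tree has no labeled leaves")

    @property
    def dendropy_tree(self) -> dendropy.Tree:
        return self._tree

    @property
    def leaf_labels(self) -> frozenset[str]:
        return frozenset(lf.taxon.label for lf in self._tree.leaf_node_iter())

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_labels)

    # -- serialization ------------------------------------------------------

    def to_newick(self) -> str:
        return self._tree.as_string(
            schema="newick",
            suppress_rooting=True,
            unquoted_underscores=True,
        ).strip() + "\n"

    def write(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_newick())

    def __str__(self) -> str:
        return self.to_newick().strip()

    def ascii_art(self) -> str:
        return self._tree.as_ascii_plot()

    # -- topology -----------------------------------------------------------

    def bipartitions(self) -> set[Split]:
        """Non-trivial splits, each canonicalized as the side without min(label).

        A split is the two-block partition of the leaf set induced by
        removing one internal edge; trivial splits (singleton sides) are not
        reported.
        """
        all_labels = self.leaf_labels
        ref = min(all_labels)
        n = len(all_labels)
        splits: set[Split] = set()
        for node in self._tree.preorder_node_iter():
            if node.parent_node is None or node.is_leaf():
                continue
            clade = frozenset(lf.taxon.label for lf in node.leaf_iter())
            if ref in clade:
                clade = frozenset(all_labels - clade)
            if 2 <= len(clade) <= n - 2:
                splits.add(clade)
        return splits

    def internal_edge_count(self) -> int:
        return len(self.bipartitions())

    def split_supports(self) -> dict[Split, float]:
        """Numeric internal-node labels read back as per-split supports."""
        all_labels = self.leaf_labels
        ref = min(all_labels)
        n = len(all_labels)
        out: dict[Split, float] = {}
        for node in self._tree.preorder_node_iter():
            if node.parent_node is None or node.is_leaf() or node.label is None:
                continue
            try:
                support = float(node.label)
            except ValueError:
                continue
            clade = frozenset(lf.taxon.label for lf in node.leaf_iter())
            if ref in clade:
                clade = frozenset(all_labels - clade)
            if 2 <= len(clade) <= n - 2:
                out[clade] = support
        return out

    def annotate_supports(self, supports: dict[Split, float]) -> None:
        """Write supports onto the internal nodes realizing each split."""
        all_labels = self.leaf_labels
        ref = min(all_labels)
        n = len(all_labels)
        for node in self._tree.preorder_node_iter():
            if node.parent_node is None or node.is_leaf():
                continue
            clade = frozenset(lf.taxon.label for lf in node.leaf_iter())
            if ref in clade:
                clade = frozenset(all_labels - clade)
            if 2 <= len(clade) <= n - 2 and clade in supports:
                v = supports[clade]
                node.label = f"{v:g}"

    def branch_lengths(self) -> list[float]:
        return [
            e.length
            for e in self._tree.preorder_edge_iter()
            if e.head_node.parent_node is not None and e.length is not None
        ]


def parse_newick(text: str) -> PhyloTree:
    """Parse a Newick string; internal node labels are kept as supports."""
    try:
        tree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises several parser error types
        raise NewickFormatError(f"malformed Newick: {exc}") from None
    return PhyloTree(tree)


def robinson_foulds(t1: PhyloTree, t2: PhyloTree) -> int:
    """Robinson–Foulds (symmetric-difference) distance between unrooted trees.

    Counts non-trivial bipartitions present in exactly one of the two trees
    (an even number whenever both trees are fully resolved).
    """
    if t1.leaf_labels != t2.leaf_labels:
        raise LeafSetMismatchError(
            f"trees have different leaf sets: "
            f"{sorted(t1.leaf_labels ^ t2.leaf_labels)} not shared"
        )
    return len(t1.bipartitions() ^ t2.bipartitions())


def _validate_nj_input(dm: DistanceMatrix) -> np.ndarray:
    if dm.n < 3:
        raise InvalidParameterError(f"neighbor joining needs >= 3 taxa, got {dm.n}")
    return dm.values.astype(np.float64, copy=True)


def neighbor_joining(dm: DistanceMatrix) -> PhyloTree:
    """Saitou–Nei neighbor joining with deterministic tie-breaking.

    Exact on additive matrices: recovers the generating topology and branch
    lengths.  On non-additive input, negative branch-length estimates are
    clamped to zero with the deficit moved to the sister branch.
    """
    d = _validate_nj_input(dm)
    tns = dendropy.TaxonNamespace(list(dm.labels))
    nodes: list[dendropy.Node] = []
    for label in dm.labels:
        node = dendropy.Node(taxon=tns.get_taxon(label))
        nodes.append(node)
    active = list(range(len(nodes)))  # indices into rows of d / nodes list

    while len(active) > 3:
        m = len(active)
        sub = d[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        # first strict minimum in row-major order = lowest creation-index pair
        flat = int(np.argmin(q))
        ai, aj = divmod(flat, m)
        if ai > aj:
            ai, aj = aj, ai
        i, j = active[ai], active[aj]
        dij = d[i, j]
        bi = 0.5 * dij + (r[ai] - r[aj]) / (2.0 * (m - 2))
        bj = dij - bi
        # clamp-and-transfer: keep bi + bj = dij, no negative branches
        if bi < 0.0:
            bj += bi
            bi = 0.0
        if bj < 0.0:
            bi += bj
            bj = 0.0
        bi, bj = max(bi, 0.0), max(bj, 0.0)
        parent = dendropy.Node()
        parent.add_child(nodes[i])
        parent.add_child(nodes[j])
        nodes[i].edge.length = bi
        nodes[j].edge.length = bj
        # distances from the new node u: d(u,k) = (d(i,k) + d(j,k) − d(i,j))/2
        new_row = 0.5 * (d[i, :] + d[j, :] - dij)
        u = len(nodes)
        nodes.append(parent)
        d = np.pad(d, ((0, 1), (0, 1)))
        d[u, :u] = new_row
        d[:u, u] = new_row
        d[u, u] = 0.0
        active = [x for x in active if x not in (i, j)] + [u]

    i, j, k = active
    center = dendropy.Node()
    closed = {
        i: 0.5 * (d[i, j] + d[i, k] - d[j, k]),
        j: 0.5 * (d[i, j] + d[j, k] - d[i, k]),
        k: 0.5 * (d[i, k] + d[j, k] - d[i, j]),
    }
    for idx in (i, j, k):
        center.add_child(nodes[idx])
        nodes[idx].edge.length = max(0.0, closed[idx])
    tree = dendropy.Tree(taxon_namespace=tns, seed_node=center)
    tree.is_rooted = False
    return PhyloTree(tree)
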