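"""Modified bootstrap on k-mer columns of the composition-vector table.

Alignment-column bootstraps do not apply to alignment-free distances, and
gene-resampling is statistically meaningless for genomes with only a handful
of genes (viruses).  The modified bootstrap instead resamples the *columns*
of the genome × k-mer table whose rows are the composition vectors X:
N = |Σ|^K columns are drawn with replacement from the full component space,
each replicate reweights the columns by its draw multiplicities, distances
are recomputed from the reweighted table, and a replicate NJ tree is built.
The support of an internal edge of the reference tree is the percentage of
replicate trees containing its bipartition.

The draw over the astronomically large zero part of the column space is
exact but collapsed: with u observed (stored-somewhere) columns, the number
of draws landing in the N − u all-zero columns is Binomial(N, 1 − u/N) and
the remaining draws are multinomial over the u observed columns.  All-zero
columns contribute nothing to sums of products, so only the observed-column
multiplicities and the fixed total weight N enter the distance algebra.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import dendropy
import numpy as np

from .composition import CompositionVector, GenomeRecord, dl_vector
from .distance import DISTANCE_METHODS, DistanceMatrix
from .errors import (
    BootstrapFailureError,
    InvalidParameterError,
    LeafSetMismatchError,
    UndefinedCorrelationError,
    UndefinedDistanceError,
)
from .njtree import PhyloTree, Split, neighbor_joining

__all__ = [
    "VectorTable",
    "SupportResult",
    "build_table",
    "resample_columns",
    "table_distance_matrix",
    "bootstrap_supports",
    "majority_rule_consensus",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True, eq=False)
class VectorTable:
    """Genome × k-mer table: one row per composition vector, columns = k-mers.

    Only the u columns in the union of stored supports are materialized
    (``codes`` / dense ``rows``); the remaining ``n_total − u`` columns are
    all-zero.  ``weights`` are the bootstrap draw multiplicities of the
    materialized columns and ``zero_draws`` the number of draws that landed
    in the all-zero complement; together they always sum to ``n_total``.
    """

    labels: tuple[str, ...]
    k: int
    n_total: int
    codes: np.ndarray  # sorted union of stored supports, shape (u,)
    rows: np.ndarray  # dense X values, shape (n_taxa, u)
    weights: np.ndarray  # int64 multiplicities, shape (u,)
    zero_draws: int

    @property
    def n_taxa(self) -> int:
        return len(self.labels)

    @property
    def n_columns(self) -> int:
        return int(self.codes.size)

    def total_multiplicity(self) -> int:
        return int(self.weights.sum()) + self.zero_draws


@dataclass(frozen=True)
class SupportResult:
    """Bootstrap outcome: annotated reference tree and per-split supports."""

    reference_tree: PhyloTree
    supports: dict[Split, float]  # split -> percentage in [0, 100]
    n_replicates: int
    n_discarded: int
    seed: int
    replicate_trees: tuple[PhyloTree, ...]

    def supports_tsv(self) -> str:
        """TSV of (bipartition, support); bipartition = sorted side labels."""
        lines = ["bipartition\tsupport"]
        for split in sorted(self.supports, key=lambda s: (len(s), sorted(s))):
            lines.append(f"{','.join(sorted(split))}\t{self.supports[split]:.1f}")
        return "\n".join(lines) + "\n"


def build_table(vectors: list[CompositionVector]) -> VectorTable:
    """Assemble composition vectors into a dense table over their union support."""
    if not vectors:
        raise InvalidParameterError("empty vector list")
    k = vectors[0].k
    alphabet = vectors[0].alphabet
    for v in vectors:
        if v.k != k or v.alphabet != alphabet:
            raise InvalidParameterError("all rows must share k and alphabet")
    labels = tuple(v.taxon_id for v in vectors)
    union = np.unique(np.concatenate([v.codes for v in vectors]))
    rows = np.zeros((len(vectors), union.size), dtype=np.float64)
    for i, v in enumerate(vectors):
        rows[i, np.searchsorted(union, v.codes)] = v.values
    n_total = alphabet.n_kmers(k)
    return VectorTable(
        labels=labels,
        k=k,
        n_total=n_total,
        codes=union,
        rows=rows,
        weights=np.ones(union.size, dtype=np.int64),
        zero_draws=n_total - union.size,
    )


def resample_columns(
    table: VectorTable,
    rng: np.random.Generator | int,
    *,
    distinct: bool = False,
) -> VectorTable:
    """One bootstrap draw of N columns with replacement from the full space.

    ``distinct=False`` (primary): every draw keeps its multiplicity, so the
    resampled table has the same total width N as the original.
    ``distinct=True`` (historical variant): columns drawn more than once are
    kept singly, giving a narrower table in which every drawn k-mer retains
    its original value exactly once.
    """
    if table.n_columns == 0:
        raise InvalidParameterError("cannot resample an empty table")
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    elif not isinstance(rng, np.random.Generator):
        raise InvalidParameterError(f"rng must be a seed or Generator, got {type(rng)!r}")
    n_total, u = table.n_total, table.n_columns
    n_zero_draws = int(rng.binomial(n_total, (n_total - u) / n_total))
    m_obs = rng.multinomial(n_total - n_zero_draws, np.full(u, 1.0 / u))
    if distinct:
        n_zero_cols = n_total - u
        if 0 < n_zero_cols <= 10**7:
            n_zero_draws = int(
                np.unique(rng.integers(n_zero_cols, size=n_zero_draws)).size
            )
        # for a vastly larger zero space, collisions among zero draws are
        # negligible and each draw is treated as a distinct column
        m_obs = (m_obs > 0).astype(np.int64)
    return VectorTable(
        labels=table.labels,
        k=table.k,
        n_total=table.n_total,
        codes=table.codes,
        rows=table.rows,
        weights=m_obs.astype(np.int64),
        zero_draws=n_zero_draws,
    )


def table_distance_matrix(table: VectorTable, method: str = "correlation") -> DistanceMatrix:
    """Distance matrix from a (possibly reweighted) vector table.

    Vectorized equivalent of the sparse pairwise functions: each materialized
    column enters with its multiplicity, the all-zero columns enter only
    through the total component count.  The total is ``weights + zero_draws``
    for a resampled table and N for the original.
    """
    if method not in DISTANCE_METHODS:
        raise InvalidParameterError(
            f"unknown distance method {method!r}; expected one of {DISTANCE_METHODS}"
        )
    w = table.weights.astype(np.float64)
    n_comp = float(table.total_multiplicity())
    rw = table.rows * w[None, :]
    gram = rw @ table.rows.T  # Σ_cols m_c · x_c · y_c
    sums = rw.sum(axis=1)  # Σ_cols m_c · x_c
    if method == "correlation":
        cov = gram - np.outer(sums, sums) / n_comp
        var = np.diag(cov).copy()
        if np.any(var <= 0.0):
            bad = [table.labels[i] for i in np.flatnonzero(var <= 0.0)]
            raise UndefinedCorrelationError(
                f"zero variance in composition vector(s): {bad}"
            )
        c = cov / np.sqrt(np.outer(var, var))
        d = (1.0 - np.clip(c, -1.0, 1.0)) / 2.0
    else:
        norms = np.diag(gram).copy()
        if np.any(norms <= 0.0):
            bad = [table.labels[i] for i in np.flatnonzero(norms <= 0.0)]
            raise UndefinedDistanceError(f"zero-norm composition vector(s): {bad}")
        cos = np.clip(gram / np.sqrt(np.outer(norms, norms)), -1.0, 1.0)
        d = np.sqrt(np.maximum(0.0, 2.0 - 2.0 * cos))
    np.fill_diagonal(d, 0.0)
    d = (d + d.T) / 2.0
    return DistanceMatrix(table.labels, d)


def bootstrap_supports(
    records: list[GenomeRecord],
    k: int,
    method: str = "correlation",
    n_replicates: int = 100,
    seed: int = 0,
    *,
    distinct: bool = False,
) -> SupportResult:
    """Reference NJ tree plus modified-bootstrap supports for its internal edges.

    Replicates whose reweighted table yields an undefined distance (zero
    variance/norm) are discarded with a warning; more than 10% discarded is a
    hard failure.  Fixed ``seed`` reproduces the result bit-exactly.
    """
    if n_replicates < 1:
        raise InvalidParameterError(f"need >= 1 replicates, got {n_replicates}")
    vectors = [dl_vector(r, k) for r in records]
    labels = [v.taxon_id for v in vectors]
    if len(set(labels)) != len(labels):
        raise InvalidParameterError(f"duplicate taxon_ids: {sorted(labels)}")
    table = build_table(vectors)
    reference = neighbor_joining(table_distance_matrix(table, method))
    ref_splits = reference.bipartitions()
    rng = np.random.default_rng(seed)
    counts: dict[Split, int] = {s: 0 for s in ref_splits}
    replicate_trees: list[PhyloTree] = []
    n_discarded = 0
    for b in range(n_replicates):
        resampled = resample_columns(table, rng, distinct=distinct)
        try:
            dm = table_distance_matrix(resampled, method)
        except (UndefinedCorrelationError, UndefinedDistanceError) as exc:
            logger.warning("bootstrap replicate %d discarded: %s", b, exc)
            n_discarded += 1
            continue
        rep_tree = neighbor_joining(dm)
        replicate_trees.append(rep_tree)
        for split in rep_tree.bipartitions() & ref_splits:
            counts[split] += 1
    if n_discarded > 0.1 * n_replicates:
        raise BootstrapFailureError(
            f"{n_discarded}/{n_replicates} bootstrap replicates discarded"
        )
    n_kept = n_replicates - n_discarded
    supports = {s: 100.0 * c / n_kept for s, c in counts.items()}
    reference.annotate_supports({s: round(v) for s, v in supports.items()})
    return SupportResult(
        reference_tree=reference,
        supports=supports,
        n_replicates=n_replicates,
        n_discarded=n_discarded,
        seed=seed,
        replicate_trees=tuple(replicate_trees),
    )


def majority_rule_consensus(trees: list[PhyloTree]) -> PhyloTree:
    """Strict-majority (> 50%) consensus tree with percentage supports.

    Splits occurring in more than half of the input trees are pairwise
    compatible, hence form a laminar family that assembles into a single
    (generally multifurcating) tree.  Each consensus edge is labeled with
    its percentage, rounded to one decimal.
    """
    if not trees:
        raise InvalidParameterError("need at least one tree")
    leaf_set = trees[0].leaf_labels
    for t in trees[1:]:
        if t.leaf_labels != leaf_set:
            raise LeafSetMismatchError("consensus requires a common leaf set")
    n_trees = len(trees)
    counts: dict[Split, int] = {}
    for t in trees:
        for split in t.bipartitions():
            counts[split] = counts.get(split, 0) + 1
    majority = [s for s, c in counts.items() if c * 2 > n_trees]
    # laminar family: nest larger sides first, then hang each leaf off the
    # smallest set containing it
    majority.sort(key=lambda s: (-len(s), sorted(s)))
    tns = dendropy.TaxonNamespace(sorted(leaf_set))
    root = dendropy.Node()
    node_of: list[tuple[Split, dendropy.Node]] = []
    for split in majority:
        parent = root
        for other, onode in node_of:  # ordered big -> small
            if split < other:
                parent = onode
        node = dendropy.Node()
        node.label = f"{100.0 * counts[split] / n_trees:.1f}"
        parent.add_child(node)
        node_of.append((split, node))
    for label in sorted(leaf_set):
        parent = root
        for split, onode in node_of:
            if label in split:
                parent = onode
        leaf = dendropy.Node(taxon=tns.get_taxon(label))
        parent.add_child(leaf)
    tree = dendropy.Tree(taxon_namespace=tns, seed_node=root)
    tree.is_rooted = False
    return PhyloTree(tree)
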