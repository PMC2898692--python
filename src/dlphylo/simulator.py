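"""Synthetic genomes with known phylogeny, for end-to-end validation.

The generator draws a random unrooted binary tree, then evolves multi-gene
genomes down it under a symmetric (Jukes–Cantor-type) substitution model
generalized to alphabet size s: along a branch of length t (expected
substitutions per site), each site independently changes with probability

    p_sub(t) = (s − 1)/s · (1 − exp(−s·t/(s − 1)))

and a changed site takes a uniform draw over the other s − 1 symbols.  Root
gene sequences are i.i.d. uniform.  The model is deliberately minimal — the
composition-vector method itself is model-free, so the simulator only needs
controllable divergence, not biological realism (no indels, no rate
heterogeneity, no compositional bias).

All randomness flows through one ``numpy`` Generator seeded per dataset, so
every dataset is exactly replayable.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import dendropy
import numpy as np

from .alphabet import Alphabet, get_alphabet
from .composition import GenomeRecord
from .distance import DistanceMatrix
from .errors import InvalidParameterError
from .njtree import PhyloTree

__all__ = [
    "SimulationConfig",
    "SimulatedDataset",
    "random_tree",
    "evolve_sequences",
    "additive_matrix_from_tree",
    "simulate_dataset",
    "substitution_probability",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one simulated dataset.

    ``branch_mean`` is the mean of the exponential branch-length
    distribution, in expected substitutions per site.
    """

    n_taxa: int = 8
    n_genes: int = 10
    gene_length: int = 2000
    alphabet: str = "protein"
    branch_mean: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_taxa < 3:
            raise InvalidParameterError(f"n_taxa must be >= 3, got {self.n_taxa}")
        if self.n_genes < 1 or self.gene_length < 1:
            raise InvalidParameterError("n_genes and gene_length must be positive")
        if self.branch_mean <= 0:
            raise InvalidParameterError("branch_mean must be > 0")
        get_alphabet(self.alphabet)  # validates the name


@dataclass(frozen=True)
class SimulatedDataset:
    """A labeled truth tree plus the genomes evolved on it."""

    true_tree: PhyloTree
    records: tuple[GenomeRecord, ...]
    config: SimulationConfig

    def write_fasta(self, directory) -> None:
        """One plain FASTA per taxon (gene_i records), plus tree and manifest."""
        from pathlib import Path

        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for rec in self.records:
            with open(directory / f"{rec.taxon_id}.fasta", "w") as fh:
                for i, seq in enumerate(rec.sequences):
                    fh.write(f">gene_{i + 1}\n")
                    for off in range(0, len(seq), 70):
                        fh.write(seq[off : off + 70] + "\n")
        self.true_tree.write(directory / "true_tree.nwk")
        with open(directory / "manifest.json", "w") as fh:
            json.dump(asdict(self.config), fh, indent=2)


def substitution_probability(t: float, s: int) -> float:
    """P(site differs after branch length t) under the symmetric s-state model."""
    return (s - 1) / s * (1.0 - np.exp(-s * t / (s - 1)))


def random_tree(
    n_taxa: int,
    seed: int | np.random.Generator,
    branch_mean: float = 0.05,
    labels: list[str] | None = None,
) -> PhyloTree:
    """Uniform random unrooted binary topology with exponential branch lengths.

    Built by sequential random attachment: starting from the 3-leaf star,
    each new leaf subdivides a uniformly chosen existing edge, which yields
    the uniform distribution over unrooted binary topologies.
    """
    if n_taxa < 3:
        raise InvalidParameterError(f"n_taxa must be >= 3, got {n_taxa}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if labels is None:
        labels = [f"T{i + 1}" for i in range(n_taxa)]
    if len(labels) != n_taxa or len(set(labels)) != n_taxa:
        raise InvalidParameterError("labels must be unique and match n_taxa")
    tns = dendropy.TaxonNamespace(labels)
    center = dendropy.Node()
    leaves = [dendropy.Node(taxon=tns.get_taxon(lab)) for lab in labels]
    edges: list[tuple[dendropy.Node, dendropy.Node]] = []  # (parent, child)
    for lf in leaves[:3]:
        center.add_child(lf)
        edges.append((center, lf))
    for lf in leaves[3:]:
        parent, child = edges[int(rng.integers(len(edges)))]
        mid = dendropy.Node()
        parent.remove_child(child)
        parent.add_child(mid)
        mid.add_child(child)
        mid.add_child(lf)
        edges.remove((parent, child))
        edges.extend([(parent, mid), (mid, child), (mid, lf)])
    tree = dendropy.Tree(taxon_namespace=tns, seed_node=center)
    tree.is_rooted = False
    # lengths drawn in deterministic preorder so topology and lengths are
    # reproducible from the seed alone
    for edge in tree.preorder_edge_iter():
        if edge.head_node.parent_node is not None:
            edge.length = float(rng.exponential(branch_mean))
    return PhyloTree(tree)


def evolve_sequences(
    tree: PhyloTree, config: SimulationConfig, rng: np.random.Generator | None = None
) -> SimulatedDataset:
    """Evolve ``n_genes`` i.i.d.-uniform root genes down the tree's branches."""
    alphabet = get_alphabet(config.alphabet)
    s = alphabet.size
    if rng is None:
        rng = np.random.default_rng(config.seed)
    dtree = tree.dendropy_tree
    root = dtree.seed_node
    genes: dict[int, list[np.ndarray]] = {
        id(root): [
            rng.integers(0, s, size=config.gene_length, dtype=np.int64)
            for _ in range(config.n_genes)
        ]
    }
    records: list[GenomeRecord] = []
    symbols = np.frombuffer(alphabet.symbols.encode(), dtype=np.uint8)
    for node in dtree.preorder_node_iter():
        if node.parent_node is not None:
            t = node.edge.length
            if t is None:
                raise InvalidParameterError("tree has a branch without length")
            p_sub = substitution_probability(float(t), s)
            parent_genes = genes[id(node.parent_node)]
            my_genes = []
            for g in parent_genes:
                child = g.copy()
                mask = rng.random(child.size) < p_sub
                n_mut = int(mask.sum())
                if n_mut:
                    # uniform over the other s-1 symbols
                    child[mask] = (
                        child[mask] + rng.integers(1, s, size=n_mut, dtype=np.int64)
                    ) % s
                my_genes.append(child)
            genes[id(node)] = my_genes
        if node.is_leaf():
            seqs = tuple(
                symbols[g].tobytes().decode("ascii") for g in genes[id(node)]
            )
            records.append(
                GenomeRecord(
                    taxon_id=node.taxon.label, sequences=seqs, alphabet=alphabet
                )
            )
    return SimulatedDataset(
        true_tree=tree, records=tuple(records), config=config
    )


def additive_matrix_from_tree(tree: PhyloTree) -> DistanceMatrix:
    """Patristic (path-length) distances between all leaf pairs.

    On the output of :func:`random_tree` this is an additive matrix, the
    regime in which neighbor joining provably recovers the tree exactly.
    """
    dtree = tree.dendropy_tree
    for edge in dtree.preorder_edge_iter():
        if edge.head_node.parent_node is not None and edge.length is None:
            raise InvalidParameterError("tree has a branch without length")
    pdm = dtree.phylogenetic_distance_matrix()
    labels = [lf.taxon.label for lf in dtree.leaf_node_iter()]
    taxa = {t.label: t for t in dtree.taxon_namespace}
    n = len(labels)
    d = np.zeros((n, n), dtype=np.float64)
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = pdm.patristic_distance(taxa[labels[i]], taxa[labels[j]])
    return DistanceMatrix(tuple(labels), d)


def simulate_dataset(config: SimulationConfig) -> SimulatedDataset:
    """Random tree + evolved genomes from one seeded generator."""
    rng = np.random.default_rng(config.seed)
    tree = random_tree(config.n_taxa, rng, branch_mean=config.branch_mean)
    return evolve_sequences(tree, config, rng=rng)
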