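"""End-to-end workflow: FASTA collection -> distances -> NJ tree -> bootstrap.

This is the programmatic equivalent of a command-line driver: a validated
:class:`RunConfig` (constructable from YAML), a FASTA collection loader, and
:func:`run_pipeline`, which writes the PHYLIP matrix, the Newick tree,
optional bootstrap outputs and a JSON manifest recording the configuration
hash, package versions and per-stage timings.  Given the same config and
seed the outputs are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml
from Bio import SeqIO

from . import __version__
from .alphabet import get_alphabet
from .bootstrap import bootstrap_supports
from .composition import GenomeRecord, dl_vector
from .distance import DISTANCE_METHODS, distance_matrix, write_phylip
from .errors import DuplicateTaxonError, InvalidParameterError
from .njtree import neighbor_joining, parse_newick, robinson_foulds

__all__ = ["RunConfig", "load_collection", "run_pipeline", "K_GUARDS"]

logger = logging.getLogger(__name__)

# Highest word lengths explored in practice: K <= 13 for nucleotide data,
# and a K <= 8 guard for protein (20^8 codes still fit int64 comfortably;
# beyond that the component space stops being informative for real genomes).
K_GUARDS = {"dna": 13, "protein": 8}


@dataclass(frozen=True)
class RunConfig:
    """Validated parameters of one pipeline run.

    ``mode='whole'`` treats each FASTA file as one whole-genome record (one
    sequence); ``mode='genes'`` treats each file as the gene/protein set of
    one taxon (k-mer counts pooled across records with the summed-window
    denominator, so no concatenation artifacts are introduced).
    """

    inputs: tuple[str, ...]  # FASTA files, or a single directory
    alphabet: str = "dna"
    mode: str = "whole"
    k: int = 5
    method: str = "correlation"
    bootstrap: int = 0  # replicate count B; 0 disables the bootstrap
    seed: int = 0
    out_dir: str = "dlphylo_out"
    manifest_tsv: str | None = None  # optional two-column taxon-name override

    def __post_init__(self) -> None:
        if not self.inputs:
            raise InvalidParameterError("no input files given")
        if not isinstance(self.inputs, tuple):
            object.__setattr__(self, "inputs", tuple(self.inputs))
        if self.mode not in ("whole", "genes"):
            raise InvalidParameterError(f"mode must be 'whole' or 'genes', got {self.mode!r}")
        if self.method not in DISTANCE_METHODS:
            raise InvalidParameterError(f"unknown distance method {self.method!r}")
        alphabet = get_alphabet(self.alphabet)  # validates name
        if self.k < 2:
            raise InvalidParameterError("k must be >= 2 (background model needs K-1 >= 1)")
        guard = K_GUARDS[alphabet.name]
        if self.k > guard:
            raise InvalidParameterError(
                f"k={self.k} exceeds the {alphabet.name} guard k <= {guard}"
            )
        if self.bootstrap < 0:
            raise InvalidParameterError("bootstrap replicate count must be >= 0")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if "inputs" in data and isinstance(data["inputs"], list):
            data["inputs"] = tuple(data["inputs"])
        return cls(**data)

    def config_hash(self) -> str:
        """Stable hash over all parameters; changes iff any parameter changes."""
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _resolve_inputs(config: RunConfig) -> list[Path]:
    paths = [Path(p) for p in config.inputs]
    if len(paths) == 1 and paths[0].is_dir():
        paths = sorted(
            p
            for p in paths[0].iterdir()
            if p.suffix.lower() in (".fa", ".fasta", ".faa", ".fna")
        )
        if not paths:
            raise InvalidParameterError(f"no FASTA files in directory {config.inputs[0]!r}")
    return paths


def _taxon_names(paths: list[Path], config: RunConfig) -> dict[str, str]:
    names = {p.stem: p.stem for p in paths}
    if config.manifest_tsv:
        with open(config.manifest_tsv) as fh:
            for line in fh:
                if line.strip():
                    stem, name = line.rstrip("\n").split("\t")[:2]
                    names[stem] = name
    return names


def load_collection(config: RunConfig) -> list[GenomeRecord]:
    """Read the FASTA collection into one GenomeRecord per file.

    taxon_id defaults to the file stem; a two-column (stem, name) TSV
    manifest can override it.  Empty files and duplicate taxon_ids are
    rejected; alphabet violations beyond the usual ambiguity characters are
    handled downstream by window masking.
    """
    alphabet = get_alphabet(config.alphabet)
    paths = _resolve_inputs(config)
    names = _taxon_names(paths, config)
    records: list[GenomeRecord] = []
    seen: set[str] = set()
    for path in paths:
        seqs = [str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")]
        if not seqs:
            raise InvalidParameterError(f"no FASTA records in {path}")
        if config.mode == "whole" and len(seqs) > 1:
            logger.warning(
                "%s holds %d records in whole mode; k-mers are pooled across them",
                path.name,
                len(seqs),
            )
        taxon = names[path.stem]
        if taxon in seen:
            raise DuplicateTaxonError(f"duplicate taxon_id {taxon!r} (file {path.name})")
        seen.add(taxon)
        records.append(GenomeRecord(taxon_id=taxon, sequences=tuple(seqs), alphabet=alphabet))
    total_seqs = sum(len(r.sequences) for r in records)
    total_res = sum(r.total_length for r in records)
    logger.info(
        "loaded %d taxa, %d sequences, %d residues", len(records), total_seqs, total_res
    )
    return records


def run_pipeline(config: RunConfig, truth_newick: str | None = None) -> dict:
    """Run distances -> NJ tree (-> bootstrap) and write all artifacts.

    Returns a manifest dict (also written to ``manifest.json``) with output
    paths, the config hash and per-stage timings.  If ``truth_newick`` (a
    path) is given, the Robinson–Foulds distance to that tree is reported.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    timings: dict[str, float] = {}

    t0 = time.perf_counter()
    records = load_collection(config)
    timings["load"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    vectors = [dl_vector(r, config.k) for r in records]
    dm = distance_matrix(records, config.k, config.method, vectors=vectors)
    timings["distances"] = time.perf_counter() - t0
    matrix_path = out / "distances.phy"
    matrix_path.write_text(write_phylip(dm))

    t0 = time.perf_counter()
    tree = neighbor_joining(dm)
    timings["nj"] = time.perf_counter() - t0
    tree_path = out / "tree.nwk"
    tree.write(tree_path)

    manifest: dict = {
        "dlphylo_version": __version__,
        "config": asdict(config),
        "config_hash": config.config_hash(),
        "n_taxa": len(records),
        "outputs": {"matrix": str(matrix_path), "tree": str(tree_path)},
    }

    if config.bootstrap > 0:
        t0 = time.perf_counter()
        result = bootstrap_supports(
            records,
            config.k,
            config.method,
            n_replicates=config.bootstrap,
            seed=config.seed,
        )
        timings["bootstrap"] = time.perf_counter() - t0
        supports_path = out / "supports.tsv"
        supports_path.write_text(result.supports_tsv())
        annotated_path = out / "tree_with_supports.nwk"
        result.reference_tree.write(annotated_path)
        manifest["outputs"]["supports"] = str(supports_path)
        manifest["outputs"]["annotated_tree"] = str(annotated_path)
        manifest["bootstrap"] = {
            "replicates": result.n_replicates,
            "discarded": result.n_discarded,
            "seed": result.seed,
        }

    if truth_newick is not None:
        truth = parse_newick(Path(truth_newick).read_text())
        manifest["rf_to_truth"] = robinson_foulds(tree, truth)

    manifest["timings_sec"] = {k: round(v, 4) for k, v in timings.items()}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return manifest
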