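"""Pairwise dissimilarities between composition vectors.

Two dissimilarities are provided, both evaluated over the *full* component
space of N = |Σ|^K k-mers (components outside a vector's stored support are
exactly zero):

* correlation distance ``D = (1 − C)/2`` where C is the centered Pearson
  sample correlation of the two vectors — the classic dynamical-language
  dissimilarity (a pseudo-distance: the triangle inequality is not
  guaranteed);
* chord distance — the Euclidean distance between the unit-normalized
  vectors, ``sqrt(2 − 2·cosθ)`` with cosθ the uncentered cosine similarity —
  a proper metric, used by the modified variant of the method.

The sparse algebra is exact: means over all N components are sums of stored
entries divided by N, and cross products over the union of stored supports
carry the analytic ``−N·mean_x·mean_y`` correction for the implicit zeros.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .composition import CompositionVector, GenomeRecord, dl_vector
from .errors import (
    DuplicateTaxonError,
    InvalidParameterError,
    PhylipFormatError,
    UndefinedCorrelationError,
    UndefinedDistanceError,
)

__all__ = [
    "DistanceMatrix",
    "pearson_correlation",
    "cosine_similarity",
    "correlation_distance",
    "chord_distance",
    "distance_matrix",
    "write_phylip",
    "read_phylip",
]

DISTANCE_METHODS = ("correlation", "chord")


@dataclass(frozen=True, eq=False)
class DistanceMatrix:
    """Labeled symmetric dissimilarity matrix with zero diagonal."""

    labels: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        if not isinstance(self.labels, tuple):
            object.__setattr__(self, "labels", tuple(self.labels))
        v = np.asarray(self.values, dtype=np.float64)
        object.__setattr__(self, "values", v)
        n = len(self.labels)
        if len(set(self.labels)) != n:
            raise DuplicateTaxonError("distance matrix labels must be unique")
        if v.shape != (n, n):
            raise InvalidParameterError(
                f"matrix shape {v.shape} does not match {n} labels"
            )
        if not np.allclose(v, v.T, atol=1e-12, rtol=0.0):
            raise InvalidParameterError("distance matrix must be symmetric")
        if not np.allclose(np.diag(v), 0.0, atol=1e-12):
            raise InvalidParameterError("distance matrix diagonal must be zero")
        if np.any(v < -1e-12):
            raise InvalidParameterError("distances must be non-negative")

    @property
    def n(self) -> int:
        return len(self.labels)

    def __getitem__(self, pair: tuple[str, str]) -> float:
        i = self.labels.index(pair[0])
        j = self.labels.index(pair[1])
        return float(self.values[i, j])

    def reordered(self, labels: list[str] | tuple[str, ...]) -> "DistanceMatrix":
        """The same distances presented in a different label order."""
        idx = [self.labels.index(lab) for lab in labels]
        return DistanceMatrix(tuple(labels), self.values[np.ix_(idx, idx)])

    def to_tsv(self) -> str:
        """Long-format TSV of pairwise distances (taxon_a, taxon_b, distance)."""
        lines = ["taxon_a\ttaxon_b\tdistance"]
        for i in range(self.n):
            for j in range(i + 1, self.n):
                lines.append(
                    f"{self.labels[i]}\t{self.labels[j]}\t{self.values[i, j]:.12g}"
                )
        return "\n".join(lines) + "\n"


def _check_compatible(x: CompositionVector, y: CompositionVector) -> None:
    if x.k != y.k or x.alphabet != y.alphabet:
        raise InvalidParameterError(
            f"vectors not comparable: ({x.taxon_id!r}, k={x.k}, {x.alphabet.name}) vs "
            f"({y.taxon_id!r}, k={y.k}, {y.alphabet.name})"
        )


def _cross_sum(x: CompositionVector, y: CompositionVector) -> float:
    """Σ_i x_i·y_i over all N components = sum over the support intersection."""
    _, ix, iy = np.intersect1d(
        x.codes, y.codes, assume_unique=True, return_indices=True
    )
    return float(np.dot(x.values[ix], y.values[iy]))


def pearson_correlation(x: CompositionVector, y: CompositionVector) -> float:
    """Centered Pearson sample correlation over all N = |Σ|^K components.

    The N components of the two composition vectors are treated as paired
    samples of two random variables.  Computed sparsely but exactly.
    """
    _check_compatible(x, y)
    n_total = float(x.n_total)
    sx, sy = float(x.values.sum()), float(y.values.sum())
    sxx = float(np.dot(x.values, x.values))
    syy = float(np.dot(y.values, y.values))
    sxy = _cross_sum(x, y)
    var_x = sxx - sx * sx / n_total
    var_y = syy - sy * sy / n_total
    if var_x <= 0.0 or var_y <= 0.0:
        raise UndefinedCorrelationError(
            f"correlation undefined for ({x.taxon_id!r}, {y.taxon_id!r}): "
            "zero variance in a composition vector"
        )
    c = (sxy - sx * sy / n_total) / math.sqrt(var_x * var_y)
    return min(1.0, max(-1.0, c))


def cosine_similarity(x: CompositionVector, y: CompositionVector) -> float:
    """Uncentered cosine over all N components (the chord-distance kernel)."""
    _check_compatible(x, y)
    nx = float(np.dot(x.values, x.values))
    ny = float(np.dot(y.values, y.values))
    if nx <= 0.0 or ny <= 0.0:
        raise UndefinedDistanceError(
            f"cosine undefined for ({x.taxon_id!r}, {y.taxon_id!r}): zero-norm vector"
        )
    c = _cross_sum(x, y) / math.sqrt(nx * ny)
    return min(1.0, max(-1.0, c))


def correlation_distance(
    x: CompositionVector, y: CompositionVector, *, centered: bool = True
) -> float:
    """D(X, Y) = (1 − C(X, Y))/2 ∈ [0, 1].

    ``centered=False`` substitutes the uncentered cosine for the Pearson
    correlation (an alternative reading of the historical method; the
    centered form is the primary definition).
    """
    c = pearson_correlation(x, y) if centered else cosine_similarity(x, y)
    return (1.0 - c) / 2.0


def chord_distance(x: CompositionVector, y: CompositionVector) -> float:
    """Euclidean distance between unit-normalized vectors, in [0, 2]."""
    c = cosine_similarity(x, y)
    return math.sqrt(max(0.0, 2.0 - 2.0 * c))


def distance_matrix(
    records: list[GenomeRecord],
    k: int,
    method: str = "correlation",
    *,
    vectors: list[CompositionVector] | None = None,
) -> DistanceMatrix:
    """All-pairs dissimilarity matrix for a genome collection.

    Builds one composition vector per record (unless precomputed ``vectors``
    are supplied) and evaluates every pair with the sparse pairwise
    functions.  Label order follows input order.
    """
    if method not in DISTANCE_METHODS:
        raise InvalidParameterError(
            f"unknown distance method {method!r}; expected one of {DISTANCE_METHODS}"
        )
    if vectors is None:
        if len(records) < 3:
            raise InvalidParameterError("need at least 3 records for a matrix")
        labels = [r.taxon_id for r in records]
        if len(set(labels)) != len(labels):
            dupes = sorted({t for t in labels if labels.count(t) > 1})
            raise DuplicateTaxonError(f"duplicate taxon_ids: {dupes}")
        vectors = [dl_vector(r, k) for r in records]
    else:
        labels = [v.taxon_id for v in vectors]
    pair_fn = correlation_distance if method == "correlation" else chord_distance
    n = len(vectors)
    d = np.zeros((n, n), dtype=np.float64)
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = pair_fn(vectors[i], vectors[j])
    return DistanceMatrix(tuple(labels), d)


# ---------------------------------------------------------------------------
# PHYLIP square distance-matrix I/O


def write_phylip(dm: DistanceMatrix, *, pad_names: bool = False) -> str:
    """Render a full square PHYLIP distance matrix (6 decimal places).

    ``pad_names=True`` writes the strict 10-character name field of classic
    PHYLIP; the default is the relaxed dialect (whitespace-separated names of
    any length), which round-trips arbitrary taxon labels.
    """
    lines = [f"{dm.n:5d}"]
    for i, label in enumerate(dm.labels):
        name = f"{label[:10]:<10}" if pad_names else label
        row = "  ".join(f"{dm.values[i, j]:.6f}" for j in range(dm.n))
        lines.append(f"{name}  {row}")
    return "\n".join(lines) + "\n"


def read_phylip(text: str) -> DistanceMatrix:
    """Parse a full square PHYLIP distance matrix (relaxed names)."""
    rows = [line for line in text.splitlines() if line.strip()]
    if not rows:
        raise PhylipFormatError("empty distance-matrix text")
    try:
        n = int(rows[0].strip())
    except ValueError:
        raise PhylipFormatError(f"malformed header line {rows[0]!r}") from None
    body = rows[1:]
    if len(body) != n:
        raise PhylipFormatError(f"header declares {n} taxa but body has {len(body)} rows")
    labels: list[str] = []
    values = np.zeros((n, n), dtype=np.float64)
    for i, line in enumerate(body):
        parts = line.split()
        if len(parts) != n + 1:
            raise PhylipFormatError(
                f"row {i + 1} has {len(parts) - 1} values; expected {n}"
            )
        labels.append(parts[0])
        try:
            values[i] = [float(v) for v in parts[1:]]
        except ValueError:
            raise PhylipFormatError(f"non-numeric distance in row {i + 1}") from None
    # floats printed at 6 dp can leave asymmetry of 1e-6 magnitude; symmetrize
    values = (values + values.T) / 2.0
    np.fill_diagonal(values, 0.0)
    return DistanceMatrix(tuple(labels), values)
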