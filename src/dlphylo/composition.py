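"""K-mer frequency profiles and dynamical-language composition vectors.

The pipeline from a genome to its composition vector is

1. :func:`count_kmers` — slide a window of length K over every sequence of
   the record, pooling counts; windows touching a non-canonical character
   (N, X, gaps, ...) are excluded from both the counts and the window total.
2. :func:`frequency_profile` — observed frequencies
   ``p(w) = n(w) / Σ_j (L_j − K + 1)`` with the pooled multi-gene window
   denominator.
3. :func:`expected_profile` — the dynamical-language background: a K-mer
   can be built by appending its last letter to its (K−1)-prefix or by
   prepending its first letter to its (K−1)-suffix, so

   ``q(s_1…s_K) = [ p(s_1…s_{K−1})·p(s_K) + p(s_1)·p(s_2…s_K) ] / 2``.

4. :func:`composition_vector` — background subtraction ``X = p/q − 1`` on
   the support of q; components with q = 0 are implicitly 0.

All maps are sparse over the full N = |Σ|^K component space; see
:mod:`dlphylo.alphabet` for the integer k-mer coding.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .alphabet import Alphabet, decode_kmers
from .errors import DegenerateProfileError, InvalidParameterError, RecordTooShortError

__all__ = [
    "GenomeRecord",
    "KmerCounts",
    "FrequencyProfile",
    "CompositionVector",
    "count_kmers",
    "frequency_profile",
    "expected_profile",
    "composition_vector",
    "dl_vector",
]


@dataclass(frozen=True)
class GenomeRecord:
    """A named taxon with one or more sequences whose k-mers are pooled.

    In whole-genome mode the record holds one sequence; in gene-set /
    proteome mode one sequence per gene or protein.  Input case is
    normalized to uppercase by the alphabet encoding.
    """

    taxon_id: str
    sequences: tuple[str, ...]
    alphabet: Alphabet

    def __post_init__(self) -> None:
        if not self.taxon_id:
            raise InvalidParameterError("taxon_id must be non-empty")
        if not isinstance(self.sequences, tuple):
            object.__setattr__(self, "sequences", tuple(self.sequences))
        if len(self.sequences) < 1:
            raise InvalidParameterError(f"record {self.taxon_id!r} has no sequences")

    @property
    def total_length(self) -> int:
        return sum(len(s) for s in self.sequences)


@dataclass(frozen=True, eq=False)
class KmerCounts:
    """Sparse k-mer occurrence counts pooled over a record's sequences.

    ``valid_windows`` is the number of length-k windows whose characters are
    all canonical; the counts sum to it exactly.
    """

    k: int
    alphabet: Alphabet
    codes: np.ndarray  # sorted unique int64 k-mer codes
    values: np.ndarray  # int64 occurrence counts, aligned with codes
    valid_windows: int

    @property
    def counts(self) -> dict[str, int]:
        """Counts keyed by k-mer string (materialized on demand)."""
        return dict(
            zip(decode_kmers(self.codes, self.k, self.alphabet), self.values.tolist())
        )


@dataclass(frozen=True, eq=False)
class FrequencyProfile:
    """Sparse map k-mer -> frequency in (0, 1]; zero-valued entries are never stored.

    ``denominator`` is the pooled window count for observed profiles and
    ``None`` for model-derived (expected) profiles.
    """

    k: int
    alphabet: Alphabet
    codes: np.ndarray
    values: np.ndarray  # float64 frequencies
    denominator: int | None

    @property
    def freqs(self) -> dict[str, float]:
        return dict(
            zip(decode_kmers(self.codes, self.k, self.alphabet), self.values.tolist())
        )

    def total(self) -> float:
        return float(self.values.sum())


@dataclass(frozen=True, eq=False)
class CompositionVector:
    """Background-subtracted k-mer vector X = p/q − 1 over N = |Σ|^k components.

    Entries are stored for every k-mer with q > 0 (which includes every
    k-mer with p > 0); all other components are implicitly zero.
    """

    taxon_id: str
    k: int
    alphabet: Alphabet
    codes: np.ndarray
    values: np.ndarray  # float64 X values
    n_total: int

    @property
    def entries(self) -> dict[str, float]:
        return dict(
            zip(decode_kmers(self.codes, self.k, self.alphabet), self.values.tolist())
        )

    def to_tsv(self) -> str:
        """Two-column (kmer, X) text for debugging and export."""
        lines = [
            f"{w}\t{v:.17g}"
            for w, v in zip(
                decode_kmers(self.codes, self.k, self.alphabet), self.values
            )
        ]
        return "\n".join(lines) + "\n"


def count_kmers(record: GenomeRecord, k: int) -> KmerCounts:
    """Count k-mer occurrences pooled over all sequences of a record.

    Windows containing any non-canonical character are dropped from both the
    numerator and the window denominator, so frequencies still sum to one.
    Sequences shorter than k contribute zero windows; if *no* sequence
    reaches length k the record is rejected.
    """
    if k < 1:
        raise InvalidParameterError(f"k must be >= 1, got {k}")
    if max((len(s) for s in record.sequences), default=0) < k:
        raise RecordTooShortError(
            f"record {record.taxon_id!r} too short for k={k}: "
            f"longest sequence has {max((len(s) for s in record.sequences), default=0)} symbols"
        )
    s = record.alphabet.size
    all_codes: list[np.ndarray] = []
    for seq in record.sequences:
        L = len(seq)
        if L < k:
            continue
        sym = record.alphabet.encode(seq)
        bad = sym < 0
        nwin = L - k + 1
        # windows with any bad character are masked out via a cumulative sum
        cb = np.concatenate(([0], np.cumsum(bad)))
        valid = (cb[k:] - cb[:-k]) == 0
        symc = np.where(bad, 0, sym).astype(np.int64)
        codes = np.zeros(nwin, dtype=np.int64)
        for j in range(k):
            codes = codes * s + symc[j : j + nwin]
        all_codes.append(codes[valid])
    pooled = (
        np.concatenate(all_codes) if all_codes else np.empty(0, dtype=np.int64)
    )
    uniq, counts = np.unique(pooled, return_counts=True)
    return KmerCounts(
        k=k,
        alphabet=record.alphabet,
        codes=uniq,
        values=counts.astype(np.int64),
        valid_windows=int(pooled.size),
    )


def frequency_profile(counts: KmerCounts) -> FrequencyProfile:
    """Observed frequencies p = n / valid_windows (pooled multi-gene form)."""
    if counts.valid_windows < 1:
        raise DegenerateProfileError(
            "no valid windows: cannot form a frequency profile"
        )
    return FrequencyProfile(
        k=counts.k,
        alphabet=counts.alphabet,
        codes=counts.codes,
        values=counts.values / counts.valid_windows,
        denominator=counts.valid_windows,
    )


def expected_profile(p_km1: FrequencyProfile, p_1: FrequencyProfile) -> FrequencyProfile:
    """Dynamical-language expected K-mer frequencies.

    ``q(s_1…s_K) = [p(s_1…s_{K−1})·p(s_K) + p(s_1)·p(s_2…s_K)] / 2``,
    the symmetric average of the two one-letter-extension constructions,
    evaluated over the support generated by observed (K−1)-mers and letters.
    """
    if p_1.k != 1:
        raise InvalidParameterError(f"letter profile must have k=1, got {p_1.k}")
    if p_km1.k < 1:
        raise InvalidParameterError("prefix/suffix profile must have k >= 1")
    if p_km1.alphabet is not p_1.alphabet and p_km1.alphabet != p_1.alphabet:
        raise InvalidParameterError("profiles built over different alphabets")
    s = p_km1.alphabet.size
    k = p_km1.k + 1
    a_codes, a_vals = p_km1.codes, p_km1.values
    c_codes, c_vals = p_1.codes, p_1.values
    # prefix extension: (K-1)-mer a followed by letter c  -> code a*s + c
    pre_codes = (a_codes[:, None] * s + c_codes[None, :]).ravel()
    pre_vals = (a_vals[:, None] * c_vals[None, :]).ravel() / 2.0
    # suffix extension: letter c followed by (K-1)-mer a  -> code c*s^(K-1) + a
    suf_codes = (c_codes[:, None] * (s ** (k - 1)) + a_codes[None, :]).ravel()
    suf_vals = (c_vals[:, None] * a_vals[None, :]).ravel() / 2.0
    codes = np.concatenate([pre_codes, suf_codes])
    vals = np.concatenate([pre_vals, suf_vals])
    uniq, inv = np.unique(codes, return_inverse=True)
    q = np.zeros(uniq.size, dtype=np.float64)
    np.add.at(q, inv, vals)
    keep = q > 0.0
    return FrequencyProfile(
        k=k, alphabet=p_km1.alphabet, codes=uniq[keep], values=q[keep], denominator=None
    )


def composition_vector(
    p_k: FrequencyProfile, q: FrequencyProfile, taxon_id: str = ""
) -> CompositionVector:
    """Background subtraction X = p/q − 1 on the support of q.

    Components outside the support of q carry no signal and are implicitly
    zero.  Every observed k-mer (p > 0) lies inside support(q) by
    construction — its prefix, suffix and end letters were all observed.
    """
    if p_k.k != q.k:
        raise InvalidParameterError(
            f"profile word lengths differ: p has k={p_k.k}, q has k={q.k}"
        )
    pos = np.searchsorted(q.codes, p_k.codes)
    # impossible by construction; a failure here means corrupted inputs
    assert pos.size == 0 or (
        pos.max(initial=0) < q.codes.size and np.array_equal(q.codes[pos], p_k.codes)
    ), "observed k-mer with zero expected frequency"
    p_full = np.zeros(q.codes.size, dtype=np.float64)
    p_full[pos] = p_k.values
    x = p_full / q.values - 1.0
    return CompositionVector(
        taxon_id=taxon_id,
        k=q.k,
        alphabet=q.alphabet,
        codes=q.codes,
        values=x,
        n_total=q.alphabet.n_kmers(q.k),
    )


def dl_vector(record: GenomeRecord, k: int) -> CompositionVector:
    """Convenience chain: record -> counts -> p, q -> composition vector.

    Requires k >= 2 (the background model needs (K−1)-mer frequencies with
    K−1 >= 1).
    """
    if k < 2:
        raise InvalidParameterError(
            f"composition vectors require k >= 2 (background model), got {k}"
        )
    p_k = frequency_profile(count_kmers(record, k))
    p_km1 = frequency_profile(count_kmers(record, k - 1))
    p_1 = frequency_profile(count_kmers(record, 1))
    q = expected_profile(p_km1, p_1)
    return composition_vector(p_k, q, taxon_id=record.taxon_id)
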