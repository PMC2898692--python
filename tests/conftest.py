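"""Shared fixtures and independent brute-force oracles.

The oracles deliberately use naive quadratic/dense algorithms over explicit
k-mer strings so they share no code path with the sparse implementations
they check.
"""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from dlphylo import DNA, PROTEIN, GenomeRecord


def naive_count_kmers(sequences, k, alphabet):
    """Character-by-character sliding-window count; returns (counts, windows)."""
    canonical = set(alphabet.symbols)
    counts: dict[str, int] = {}
    windows = 0
    for seq in sequences:
        seq = seq.upper()
        for i in range(len(seq) - k + 1):
            w = seq[i : i + k]
            if all(ch in canonical for ch in w):
                counts[w] = counts.get(w, 0) + 1
                windows += 1
    return counts, windows


def dense_dl_vector(record: GenomeRecord, k: int) -> np.ndarray:
    """Dense X over all |Σ|^k components in alphabetical k-mer order.

    Recomputes p, q and X from scratch with dictionaries and an explicit
    loop over every possible k-mer; only usable for small |Σ|^k.
    """
    alphabet = record.alphabet

    def freqs(kk):
        c, w = naive_count_kmers(record.sequences, kk, alphabet)
        return {m: n / w for m, n in c.items()}, w

    p_k, _ = freqs(k)
    p_km1, _ = freqs(k - 1)
    p_1, _ = freqs(1)
    x = np.zeros(alphabet.size**k)
    for i, mer in enumerate(
        "".join(t) for t in itertools.product(alphabet.symbols, repeat=k)
    ):
        q = (
            p_km1.get(mer[:-1], 0.0) * p_1.get(mer[-1], 0.0)
            + p_1.get(mer[0], 0.0) * p_km1.get(mer[1:], 0.0)
        ) / 2.0
        if q > 0.0:
            x[i] = p_k.get(mer, 0.0) / q - 1.0
    return x


def dense_pearson(x: np.ndarray, y: np.ndarray) -> float:
    xc, yc = x - x.mean(), y - y.mean()
    return float(np.dot(xc, yc) / np.sqrt(np.dot(xc, xc) * np.dot(yc, yc)))


def dense_chord(x: np.ndarray, y: np.ndarray) -> float:
    xn = x / np.linalg.norm(x)
    yn = y / np.linalg.norm(y)
    return float(np.linalg.norm(xn - yn))


def random_record(rng, alphabet, taxon_id="t", n_seqs=1, min_len=20, max_len=60):
    """A record of uniform-random sequences over the given alphabet."""
    seqs = tuple(
        "".join(rng.choice(list(alphabet.symbols), size=rng.integers(min_len, max_len + 1)))
        for _ in range(n_seqs)
    )
    return GenomeRecord(taxon_id=taxon_id, sequences=seqs, alphabet=alphabet)


@pytest.fixture
def rng():
    return np.random.default_rng(20260918)


@pytest.fixture
def mama():
    """The hand-computed protein worked example."""
    return GenomeRecord("mama", ("MAMA",), PROTEIN)


@pytest.fixture
def dna_records(rng):
    """Three random DNA records, valid at k=3 (N=64, dense-oracle territory)."""
    return [
        random_record(rng, DNA, taxon_id=f"g{i}", min_len=100, max_len=200)
        for i in range(3)
    ]
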