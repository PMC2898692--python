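"""Sequence alphabets and integer k-mer coding.

K-mers are carried internally as base-``|Σ|`` integer codes in int64 numpy
arrays: a k-mer ``s_1 … s_k`` maps to ``Σ_j index(s_j)·|Σ|^(k−j)``.  This keeps
DNA up to K = 13 (4^13 ≈ 6.7e7) and protein up to K = 8 (20^8 ≈ 2.6e10)
inside int64 with room to spare, and lets all sparse-vector algebra run as
vectorized array operations.  Human-readable k-mer strings are recovered on
demand with :func:`decode_kmers`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidParameterError

__all__ = ["Alphabet", "DNA", "PROTEIN", "get_alphabet", "decode_kmer", "decode_kmers"]


@dataclass(frozen=True)
class Alphabet:
    """An ordered set of canonical sequence symbols.

    Parameters
    ----------
    name
        ``"dna"`` or ``"protein"``.
    symbols
        The canonical characters in their fixed (alphabetical) order; this
        order defines the k-mer indexing of the composition-vector space.
    """

    name: str
    symbols: str
    _lut: np.ndarray = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        if len(set(self.symbols)) != len(self.symbols):
            raise InvalidParameterError("alphabet symbols must be unique")
        if self.symbols != self.symbols.upper():
            raise InvalidParameterError("alphabet symbols must be uppercase")
        # char byte -> symbol index, -1 for anything non-canonical; lowercase
        # letters map to their uppercase index so input case never matters.
        lut = np.full(256, -1, dtype=np.int8)
        for i, ch in enumerate(self.symbols):
            lut[ord(ch)] = i
            lut[ord(ch.lower())] = i
        object.__setattr__(self, "_lut", lut)

    @property
    def size(self) -> int:
        return len(self.symbols)

    def n_kmers(self, k: int) -> int:
        """Size N = |Σ|^k of the full k-mer component space."""
        return self.size**k

    def encode(self, sequence: str) -> np.ndarray:
        """Map a sequence to symbol indices; non-canonical characters become -1."""
        raw = np.frombuffer(sequence.encode("ascii", errors="replace"), dtype=np.uint8)
        return self._lut[raw]


DNA = Alphabet("dna", "ACGT")
PROTEIN = Alphabet("protein", "ACDEFGHIKLMNPQRSTVWY")

_BY_NAME = {"dna": DNA, "protein": PROTEIN}


def get_alphabet(name: str) -> Alphabet:
    try:
        return _BY_NAME[name.lower()]
    except KeyError:
        raise InvalidParameterError(
            f"unknown alphabet {name!r}; expected 'dna' or 'protein'"
        ) from None


def decode_kmer(code: int, k: int, alphabet: Alphabet) -> str:
    """Inverse of the base-|Σ| coding for a single k-mer."""
    s = alphabet.size
    chars = []
    for _ in range(k):
        code, r = divmod(code, s)
        chars.append(alphabet.symbols[r])
    return "".join(reversed(chars))


def decode_kmers(codes: np.ndarray, k: int, alphabet: Alphabet) -> list[str]:
    return [decode_kmer(int(c), k, alphabet) for c in codes]
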