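"""Exception hierarchy for dlphylo.

Every failure mode named in the module contracts maps to one class here so
callers can catch by situation rather than parsing messages.
"""


class DLPhyloError(Exception):
    """Base class for all dlphylo errors."""


class InvalidParameterError(DLPhyloError, ValueError):
    """A parameter violates its contract (k < 1, mismatched word lengths, ...)."""


class RecordTooShortError(DLPhyloError, ValueError):
    """No sequence in the record is long enough to yield a single k-window."""


class DegenerateProfileError(DLPhyloError, ValueError):
    """A frequency profile cannot be formed (zero valid windows)."""


class UndefinedCorrelationError(DLPhyloError, ArithmeticError):
    """Pearson correlation undefined: one of the vectors has zero variance."""


class UndefinedDistanceError(DLPhyloError, ArithmeticError):
    """Chord distance undefined: one of the vectors has zero norm."""


class DuplicateTaxonError(DLPhyloError, ValueError):
    """Two records in a collection share a taxon_id."""


class LeafSetMismatchError(DLPhyloError, ValueError):
    """Two trees compared on different leaf sets."""


class PhylipFormatError(DLPhyloError, ValueError):
    """Malformed PHYLIP distance-matrix text."""


class NewickFormatError(DLPhyloError, ValueError):
    """Malformed Newick tree text."""


class BootstrapFailureError(DLPhyloError, RuntimeError):
    """More than 10% of bootstrap replicates produced undefined distances."""
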