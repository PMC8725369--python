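"""Exception hierarchy for regenmeth.

All library errors derive from :class:`RegenmethError` so callers can catch
pipeline failures with a single except clause while still distinguishing
format problems from statistical degeneracies.
"""


class RegenmethError(Exception):
    """Base class for all regenmeth errors."""


class FormatError(RegenmethError):
    """A file does not conform to the expected on-disk dialect."""


class ValidationError(RegenmethError):
    """An in-memory object violates its invariants (bad counts, bad config)."""


class ContextError(RegenmethError):
    """A trinucleotide cannot be classified into CpG/CHG/CHH."""


class NormalizationError(RegenmethError):
    """A track or matrix normalization total is zero or undefined."""


class AlignmentError(RegenmethError):
    """Two tracks or matrices that must share shape/coordinates do not."""


class DegenerateVarianceError(RegenmethError):
    """A variance estimate required by a test is zero or undefined."""


class DegenerateTableError(RegenmethError):
    """A contingency table has a zero row or column margin."""


class SizingError(RegenmethError):
    """Requested genome geometry does not fit (too many genes, short chrom)."""
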