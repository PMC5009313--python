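"""Exception hierarchy for array-BSA analyses.

Every error raised deliberately by this package derives from
:class:`ArrayBSAError`, so callers can catch pipeline failures without
masking programming errors.
"""


class ArrayBSAError(Exception):
    """Base class for all errors raised by arraybsa."""


class FormatError(ArrayBSAError, ValueError):
    """A delimited input file is missing required columns or is malformed."""


class AnnotationMismatchError(ArrayBSAError, ValueError):
    """A scan table refers to a feature absent from the array layout."""


class DuplicateReplicateError(ArrayBSAError, ValueError):
    """Two hybridizations share the same (target, bio, tech) replicate key."""


class AlignmentError(ArrayBSAError, ValueError):
    """Fingerprints to be combined do not share a common feature set."""


class DegenerateBackgroundError(ArrayBSAError, ZeroDivisionError):
    """Background SD is zero, so a signal-to-noise ratio is undefined."""


class NormalizationError(ArrayBSAError, ValueError):
    """Spike-in control unusable (masked or non-positive) in a hybridization."""


class InsufficientDataError(ArrayBSAError, ValueError):
    """Too few observations for the requested statistic."""


class DegenerateDataError(ArrayBSAError, ValueError):
    """Zero total variance / singular scatter matrix where positive definite
    structure is required."""


class DomainError(ArrayBSAError, ValueError):
    """A value lies outside its scientifically meaningful domain
    (e.g. a flowering score outside 1-4, an allele dosage above the ploidy)."""
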