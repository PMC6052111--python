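"""Exception hierarchy for the toolkit."""


class CoexnetError(Exception):
    """Base class for all toolkit errors."""


class IdentifierCollisionError(CoexnetError):
    """Duplicate gene or sample identifiers in an input file."""


class ParseError(CoexnetError):
    """Malformed input file (non-numeric cell, missing column, ...)."""


class EmptyMatrixError(CoexnetError):
    """An operation left no genes (or no samples) in the matrix."""


class MissingLengthError(CoexnetError):
    """A gene has no transcript length for TPM normalization."""


class ZeroLibraryError(CoexnetError):
    """A sample has zero total counts and cannot be TPM-normalized."""


class DomainError(CoexnetError):
    """A value is outside the mathematical domain of the transform."""


class ZeroVarianceError(CoexnetError):
    """A zero-variance gene or sample where variance is required."""


class InsufficientSamplesError(CoexnetError):
    """Too few samples for the requested statistic."""


class EmptyAnnotationError(CoexnetError):
    """No annotation term survived filtering."""


class AmbiguousAssignmentError(CoexnetError):
    """A guide gene is listed under conflicting sub-pathway labels."""


class KindMismatchError(CoexnetError):
    """A ScoreMatrix of the wrong kind was passed to an operation."""


class ParameterError(CoexnetError):
    """An out-of-range or inconsistent parameter value."""


class ConditioningError(CoexnetError):
    """A shrunken covariance matrix is numerically singular."""


class UndefinedStatisticError(CoexnetError):
    """The requested statistic is undefined on these inputs (e.g. no
    annotated gene in the network, no positive instance for an AUROC)."""


class EmptyPlcError(CoexnetError):
    """No guide gene of the pathway is present in the network."""


class DegenerateTableError(CoexnetError):
    """A contingency table too small for the Chi-squared statistic."""


class LabelError(CoexnetError):
    """A partition does not cover every vertex of its graph."""
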