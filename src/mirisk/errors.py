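"""Exception hierarchy. Every category of data/contract failure gets its own type
so the CLI can map failures to exit codes and users can catch precisely."""


class MiriskError(Exception):
    """Base class for all package errors."""


class IdentifierError(MiriskError):
    """Duplicate or otherwise invalid probe/sample identifiers."""


class ParseError(MiriskError):
    """Malformed cell or line in an input file."""


class SchemaError(MiriskError):
    """Missing column or unknown enum label in an annotation file."""


class ValidationError(MiriskError):
    """A record violates a domain invariant (e.g. non-positive survival time)."""


class AlignmentError(MiriskError):
    """Sample/probe universes do not overlap as required."""


class ConfigError(MiriskError):
    """Invalid simulation or pipeline configuration."""


class DomainError(MiriskError):
    """Numeric input outside the mathematical domain of an operation."""


class NormalizationError(MiriskError):
    """Invariant probe set too small or mapping not fittable."""


class DesignError(MiriskError):
    """Differential-expression design not estimable."""


class DegenerateVarianceError(MiriskError):
    """All residual variances are numerically zero."""


class FitError(MiriskError):
    """Survival model cannot be fit (no events, ...)."""


class DivergenceError(FitError):
    """Newton iteration diverged or information matrix is singular."""


class GroupingError(MiriskError):
    """Group structure invalid for a two-group test."""


class CutpointError(MiriskError):
    """No admissible candidate cutoffs for maxstat."""


class SignatureError(MiriskError):
    """Risk-signature construction or application failed."""


class TargetScoreError(SignatureError):
    """Too few mapped target genes to build a target score."""


class AssociationError(MiriskError):
    """Global association test not computable (constant outcome, ...)."""


class DissimilarityError(MiriskError):
    """Zero-variance sample in a correlation-based dissimilarity."""
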