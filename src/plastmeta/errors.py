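"""Exception hierarchy with machine-readable error codes.

Every pipeline-level failure carries a short ``code`` so batch runs can log
and classify per-comparison errors without string matching.
"""


class PlastmetaError(Exception):
    """Base class for all package errors."""

    code = "error"


class FormatError(PlastmetaError):
    """An input file does not match the documented schema."""

    code = "format"


class StructureError(PlastmetaError):
    """A comparison is structurally incomplete (e.g. a missing unit)."""

    code = "structure"


class MetadataError(PlastmetaError):
    """Trait present in the data but absent from the trait metadata."""

    code = "metadata"


class DegenerateTraitError(PlastmetaError):
    """A trait has zero pooled variance and cannot be standardized."""

    code = "degenerate_trait"


class DegenerateMatrixError(PlastmetaError):
    """A covariance matrix is degenerate for the requested statistic."""

    code = "degenerate_matrix"


class InsufficientSampleError(PlastmetaError):
    """Too few individuals (or effects) for the requested computation."""

    code = "insufficient_sample"


class UndefinedAngleError(PlastmetaError):
    """An angle involving a (near-)zero vector is undefined."""

    code = "undefined_angle"


class UnstableEffectError(PlastmetaError):
    """Too many Monte-Carlo replicates of an effect size were undefined."""

    code = "unstable_effect"


class NumericError(PlastmetaError):
    """A numerical precondition (e.g. positive semi-definiteness) failed."""

    code = "numeric"


class ConvergenceError(PlastmetaError):
    """REML optimization failed to converge after all restarts."""

    code = "convergence"


class ValidationError(PlastmetaError):
    """An input object violates a documented invariant."""

    code = "validation"


class MissingDataError(PlastmetaError):
    """Required data (e.g. fitness observations) are absent."""

    code = "missing_data"
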