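"""Exception hierarchy.

Every failure mode the library promises to detect maps onto one of these, so
callers (and the CLI) can categorize errors without string matching.
"""


class HemoflowError(Exception):
    """Base class for all package errors."""


class InvalidGeometryError(HemoflowError):
    """Lesion/vessel geometry violates a geometric invariant."""


class NoLesionError(InvalidGeometryError):
    """Geometry contains no detectable lesion."""


class AmbiguousLesionError(InvalidGeometryError):
    """Geometry contains more than one disjoint lesion."""


class InputError(HemoflowError, ValueError):
    """A scalar/array argument violates a precondition."""


class ConfigurationError(HemoflowError):
    """Invalid configuration; carries the offending field path."""

    def __init__(self, message: str, field: str | None = None):
        self.field = field
        super().__init__(f"{field}: {message}" if field else message)


class RegimeError(HemoflowError):
    """Flow conditions outside the laminar steady regime the solver supports."""


class ConvergenceError(HemoflowError):
    """Iterative solve failed to converge; carries the final residual."""

    def __init__(self, message: str, final_residual: float | None = None,
                 iterations: int | None = None):
        self.final_residual = final_residual
        self.iterations = iterations
        super().__init__(message)


class UnconvergedFieldError(HemoflowError):
    """Refused to post-process an unconverged flow field."""


class StatisticsError(HemoflowError, ValueError):
    """A statistical routine received degenerate input."""


class ConstantInputError(StatisticsError):
    """Correlation undefined because an input vector is constant."""


class DegenerateAdjustmentError(StatisticsError):
    """Covariate adjustment impossible (collinear covariates)."""


class SubgroupSizeError(StatisticsError):
    """A subgroup is too small for the requested analysis."""


class EmptyCohortError(HemoflowError):
    """No lesion survived exclusions/solves."""
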