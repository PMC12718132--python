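"""Exception hierarchy shared across the analysis stages."""


class SmstoichError(Exception):
    """Base class for package errors."""


class InvalidParameterError(SmstoichError, ValueError):
    """A parameter violates its documented domain (negative rate, zero area, ...)."""


class InsufficientDataError(SmstoichError, ValueError):
    """Too few samples / groups / points for the requested fit or test."""


class DegenerateVarianceError(SmstoichError, ValueError):
    """All values identical: a log-normal scale parameter cannot be estimated.

    The geometric mean is still well defined and is attached as
    ``geometric_mean`` on the exception instance.
    """

    def __init__(self, message: str, geometric_mean: float | None = None):
        super().__init__(message)
        self.geometric_mean = geometric_mean


class FitFailureError(SmstoichError, RuntimeError):
    """An iterative fit did not converge; diagnostics attached as ``details``."""

    def __init__(self, message: str, details: dict | None = None):
        super().__init__(message)
        self.details = details or {}


class UncorrectableTrendError(SmstoichError, ValueError):
    """A baseline trend cannot be estimated from the stimulus-free samples."""


class ValidationError(SmstoichError, ValueError):
    """Pre-flight validation of a pipeline run configuration failed."""
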