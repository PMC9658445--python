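"""Exception hierarchy shared across the package."""


class TrailmetricsError(Exception):
    """Base class for all package errors."""


class ValidationError(TrailmetricsError, ValueError):
    """An input violates a documented precondition."""


class FormatError(TrailmetricsError, ValueError):
    """A file does not conform to the expected layout."""


class FitError(TrailmetricsError, RuntimeError):
    """A model fit failed an acceptance gate (e.g. low R²)."""


class ConvergenceError(TrailmetricsError, RuntimeError):
    """An iterative solver did not converge within its budget."""
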