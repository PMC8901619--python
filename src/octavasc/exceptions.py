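"""Exception hierarchy for octavasc.

All errors raised by the library derive from :class:`OctavascError` so callers
can catch pipeline failures with a single except clause while still
distinguishing contract violations (``ValueError`` subclasses) from runtime
failures (``RuntimeError`` subclasses).
"""


class OctavascError(Exception):
    """Base class for all octavasc errors."""


class NoContrastError(OctavascError, ValueError):
    """Raised when a global threshold is requested for a constant image."""


class ConvergenceError(OctavascError, RuntimeError):
    """Raised when an iterative threshold fails to converge.

    Carries the last iterate in ``last_iterate`` for diagnostics.
    """

    def __init__(self, message: str, last_iterate: float | None = None):
        super().__init__(message)
        self.last_iterate = last_iterate


class QualityError(OctavascError, ValueError):
    """Raised when an image fails the signal-strength quality gate."""


class LayerError(OctavascError, ValueError):
    """Raised when an operation receives an image of the wrong anatomical layer."""


class UndefinedMetricError(OctavascError, ValueError):
    """Raised when a metric is undefined for the given input (e.g. empty skeleton)."""


class GenerationError(OctavascError, RuntimeError):
    """Raised when a synthetic-data generator cannot satisfy its request."""


class InsufficientDataError(OctavascError, ValueError):
    """Raised when a statistical procedure has too little support to run."""


class CollinearityError(OctavascError, ValueError):
    """Raised when a regression design matrix is (numerically) collinear."""
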