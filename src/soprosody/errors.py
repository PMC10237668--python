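"""Exception hierarchy for soprosody."""


class SoprosodyError(Exception):
    """Base class for all package errors."""


class ContourError(SoprosodyError):
    """Invalid f0 contour (too few samples, non-finite values)."""


class OrderingError(ContourError):
    """Contour times are not strictly increasing."""


class GridError(SoprosodyError):
    """Normalized contours or model curves live on incompatible grids."""


class RankError(SoprosodyError):
    """Requested more components than the centered data support."""


class ConditionError(SoprosodyError):
    """Unknown prosody condition label."""


class DegenerateTokenError(SoprosodyError):
    """Segmented token has zero total duration."""


class SchemaError(SoprosodyError):
    """A table is missing required columns or metadata."""


class ConvergenceError(SoprosodyError):
    """MCMC convergence contract violated; carries the diagnostic report."""

    def __init__(self, message, report=None):
        super().__init__(message)
        self.report = report


class InstabilityError(SoprosodyError):
    """Bridge-sampling estimate too variable across repeats."""


class CapabilityError(SoprosodyError):
    """Requested a summary the fitted model cannot provide."""
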