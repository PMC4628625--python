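"""Exception hierarchy for fractaldiff.

All domain errors derive from :class:`FractalDiffError` so callers (and the
CLI) can distinguish bad physics/data from programming errors.
"""


class FractalDiffError(Exception):
    """Base class for all fractaldiff domain errors."""


class InvalidParameterError(FractalDiffError, ValueError):
    """A model parameter violates its physical constraints (e.g. tau <= 0)."""


class InvalidInputError(FractalDiffError, ValueError):
    """An input value is outside the operation's domain (e.g. negative MSD)."""


class SingularExponentError(FractalDiffError, ValueError):
    """An expression is singular at the requested exponent (alpha = 1)."""


class DegenerateDataError(FractalDiffError, ValueError):
    """Data points are degenerate for the requested estimator
    (e.g. two MSD points implying purely ballistic scaling)."""


class InconsistentDataError(FractalDiffError, ValueError):
    """Data are mutually inconsistent with the assumed model
    (e.g. a negative mean-free-path estimate)."""


class InfeasibleObservationError(FractalDiffError, ValueError):
    """An observation lies outside the model's reachable range
    (e.g. MSD at or above the ballistic bound)."""


class NoSolutionError(FractalDiffError, RuntimeError):
    """A root/parameter search found no solution in the scanned interval."""

    def __init__(self, message: str, interval=None):
        super().__init__(message)
        self.interval = interval


class NumericalError(FractalDiffError, RuntimeError):
    """A numerical routine failed to converge; carries bracket state."""

    def __init__(self, message: str, bracket=None):
        super().__init__(message)
        self.bracket = bracket


class InsufficientDataError(FractalDiffError, ValueError):
    """Too few data points for the requested fit."""


class InsufficientSpanError(FractalDiffError, ValueError):
    """A requested lag meets or exceeds the trajectory's time span."""
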