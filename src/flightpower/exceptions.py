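"""Exception hierarchy for the flightpower package."""


class FlightPowerError(Exception):
    """Base class for all package errors."""


class InvalidInputError(FlightPowerError, ValueError):
    """A physically or numerically invalid input (non-positive mass, speed, ...)."""


class ShapeError(FlightPowerError, ValueError):
    """Gridded inputs with inconsistent shapes or coordinates."""


class ResolutionError(FlightPowerError, ValueError):
    """Grid too coarse for the requested differential operator."""


class InsufficientDataError(FlightPowerError, ValueError):
    """Fewer samples/frames than the operation requires."""


class NoMinimumError(FlightPowerError, RuntimeError):
    """Power curve has no interior minimum on the bracketing interval."""


class ConvergenceError(FlightPowerError, RuntimeError):
    """An iterative solve failed to converge; carries diagnostics."""

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


class FitQualityError(FlightPowerError, RuntimeError):
    """A regression fit is degenerate or fails quality checks."""


class IdentifiabilityError(FlightPowerError, RuntimeError):
    """Design matrix is rank deficient; model parameters not identifiable."""
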