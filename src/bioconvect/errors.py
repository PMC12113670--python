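"""Exception hierarchy for the solver."""


class BioconvectError(Exception):
    """Base class for all package errors."""


class InvalidInputError(BioconvectError, ValueError):
    """A parameter or field value violates its contract."""


class InvalidGridError(InvalidInputError):
    """Grid construction with too few points or bad aspect ratio."""


class InvalidSourceError(InvalidInputError):
    """A thermal-source segment lies outside the wall or is degenerate."""


class ConfigError(BioconvectError, ValueError):
    """A configuration file failed to parse or contains unknown keys."""


class SingularSystemError(BioconvectError, ArithmeticError):
    """Tridiagonal elimination hit a zero pivot."""


class UnstableStepError(BioconvectError, ArithmeticError):
    """An implicit line system lost diagonal dominance (time step too large)."""


class IterativeFailureError(BioconvectError, ArithmeticError):
    """An iterative solve failed to reach its residual tolerance."""

    def __init__(self, message: str, residual: float | None = None):
        super().__init__(message)
        self.residual = residual


class DivergenceError(BioconvectError, ArithmeticError):
    """A field became non-finite during time stepping."""

    def __init__(self, field: str):
        super().__init__(f"non-finite values detected in field '{field}'")
        self.field = field


class InsufficientDataError(BioconvectError, ValueError):
    """Not enough sweep points to estimate an onset value."""
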