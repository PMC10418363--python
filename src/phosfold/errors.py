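"""Exception hierarchy shared across the pipeline stages."""


class PhosfoldError(Exception):
    """Base class for all package errors."""


class ParseError(PhosfoldError):
    """Malformed structure file (carries the offending line number)."""

    def __init__(self, message: str, line_number: int | None = None):
        self.line_number = line_number
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)


class ValidationError(PhosfoldError):
    """Invalid configuration or input that fails a precondition."""


class GeometryError(PhosfoldError):
    """Geometrically impossible or degenerate input (overlaps, out-of-grid atoms)."""


class ParameterizationError(PhosfoldError):
    """Residue or atom missing from the parameter table."""


class ConvergenceError(PhosfoldError):
    """Iterative solver failed to reach the requested residual."""

    def __init__(self, message: str, residual: float | None = None):
        self.residual = residual
        super().__init__(message)
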