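"""Exception hierarchy shared across the package."""


class SympatryError(Exception):
    """Base class for package errors."""


class ConfigurationError(SympatryError):
    """Invalid run configuration or file dialect (e.g. a missing column)."""


class RowError(SympatryError):
    """A data row that cannot be interpreted; carries the 1-based line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class ValidationError(SympatryError):
    """Input values outside their documented domain."""


class DegenerateError(SympatryError):
    """A computation whose preconditions hold but whose data are degenerate
    (e.g. no eligible velocity pair, >50% of fixes flagged as excursions)."""
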