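"""Exception types shared across the package."""


class ChanpredError(Exception):
    """Base class for package errors."""


class FastaParseError(ChanpredError):
    """Malformed FASTA input (e.g. sequence data before any header line)."""

    def __init__(self, message: str, line_number: int | None = None):
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)
        self.line_number = line_number


class ConfigurationError(ChanpredError):
    """Invalid configuration value (bad label scheme, empty grid, ...)."""


class InputDataError(ChanpredError):
    """Input data violates a precondition (dimension mismatch, tiny class, ...)."""
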