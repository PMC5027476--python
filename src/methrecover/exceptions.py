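"""Exception hierarchy shared across the package."""


class MethRecoverError(ValueError):
    """Base class for all errors raised by this package."""


class ParseError(MethRecoverError):
    """A file could not be parsed (malformed line, bad header, ragged row)."""

    def __init__(self, message: str, line_number: int | None = None):
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)
        self.line_number = line_number


class ValidationError(MethRecoverError):
    """Inputs violated a documented contract (coordinates, roles, thresholds)."""
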