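"""Exception hierarchy shared across the package."""


class MPNSTKitError(Exception):
    """Base class for all package errors."""


class ConfigurationError(MPNSTKitError):
    """Invalid configuration value (bad proportion, count, hazard, ...)."""


class DataError(MPNSTKitError):
    """Malformed or degenerate input data."""


class ArgumentError(MPNSTKitError):
    """Invalid argument combination passed to an operation."""


class ParseError(DataError):
    """A text input file could not be parsed; carries file and line context."""

    def __init__(self, message: str, path=None, line_no: int | None = None):
        ctx = ""
        if path is not None:
            ctx += f" [{path}"
            if line_no is not None:
                ctx += f":{line_no}"
            ctx += "]"
        super().__init__(message + ctx)
        self.path = path
        self.line_no = line_no
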