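"""Exception hierarchy shared across the package."""


class MQTLError(Exception):
    """Base class for all package errors."""


class ParseError(MQTLError):
    """A file could not be parsed; carries the offending line number when known."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class ValidationError(MQTLError):
    """A record violates an invariant."""


class StandardizationError(MQTLError):
    """A QTL record lacks the statistics needed to fill LOD/R2/CI."""


class ProjectionError(MQTLError):
    """A map or QTL could not be projected onto the reference."""
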