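"""Exception types shared across the package."""


class OxbsError(Exception):
    """Base class for package errors."""


class ConfigError(OxbsError):
    """Invalid configuration (bad sizes, missing fields, conflicting options)."""


class AlignmentError(OxbsError):
    """Matrices that must share probe/sample indices do not."""


class EmptyResultError(OxbsError):
    """An operation removed or received all rows/columns."""


class ValidationError(OxbsError):
    """A value is outside its admissible domain."""


class TrackError(OxbsError):
    """An interval track or transcript model is malformed."""


class ParseError(OxbsError):
    """A file could not be parsed; carries the offending line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"{message} (line {line})"
        super().__init__(message)
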