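"""Exception hierarchy shared across the package."""


class GCScreenError(Exception):
    """Base class for all package errors."""


class ValidationError(GCScreenError):
    """An object or file violates a structural invariant (ordering, lengths, signs)."""


class ParseError(GCScreenError):
    """A file could not be parsed under the declared format."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class ConfigurationError(GCScreenError):
    """The requested operation cannot run with the supplied configuration."""


class NotFoundError(GCScreenError):
    """An expected feature (e.g. a peak near a retention time) was not found."""


class AmbiguityError(GCScreenError):
    """More than one candidate feature satisfies the request."""

    def __init__(self, message: str, candidates=None):
        self.candidates = list(candidates or [])
        super().__init__(message)
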