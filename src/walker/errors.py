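"""Exception hierarchy shared across the package."""


class WalkerError(Exception):
    """Base class for all errors raised by this package."""


class AnnotationParseError(WalkerError):
    """A line of an annotation or evidence file could not be parsed.

    Carries the 1-based line number when known.
    """

    def __init__(self, message: str, line_number: int | None = None):
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)
        self.line_number = line_number


class ValidationError(WalkerError):
    """An object violates a structural invariant (e.g. overlapping exons)."""


class EmptyInputError(WalkerError):
    """An input that must contain at least one record was empty."""
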