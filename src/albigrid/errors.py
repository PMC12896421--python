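"""Exception types shared across the package."""


class AlbigridError(Exception):
    """Base class for package errors."""


class InvalidInputError(AlbigridError, ValueError):
    """A laboratory value or parameter violates its domain constraints."""


class NotClassifiableError(AlbigridError, ValueError):
    """The zone rules make no grade claim for this input (sentinel zone)."""


class NotApplicableError(AlbigridError, ValueError):
    """The requested analysis is undefined for this zone."""


class UnsupportedStepError(AlbigridError, ValueError):
    """Grid step is not a positive multiple of the 0.1 reporting increment."""


class CohortParseError(AlbigridError, ValueError):
    """A cohort CSV row could not be parsed; carries the 1-based line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)
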