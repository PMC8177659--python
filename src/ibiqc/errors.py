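"""Exception types shared across the package."""


class IbiqcError(Exception):
    """Base class for package errors."""


class TraceParseError(IbiqcError, ValueError):
    """A trace or activity file could not be parsed.

    Carries the 1-based line number of the offending record when known.
    """

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class TraceValidationError(IbiqcError, ValueError):
    """A trace violates a structural invariant (ordering, positivity...)."""


class SpecError(IbiqcError, ValueError):
    """A generator / corruption / correction configuration is invalid."""


class InsufficientDataError(IbiqcError, ValueError):
    """Too few usable beats for the requested statistic."""
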