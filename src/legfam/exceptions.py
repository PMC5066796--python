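"""Exception hierarchy for the pipeline."""


class LegfamError(Exception):
    """Base class for all package errors."""


class CapacityError(LegfamError):
    """Raised when gene placement cannot fit within the chromosomes."""


class DesignError(LegfamError):
    """Raised for invalid experimental designs (e.g. zero replicates)."""


class BackendUnavailableError(LegfamError):
    """An external executable backend is missing.

    Carries the name of the internal fallback so callers can recover.
    """

    def __init__(self, backend: str, fallback: str = "internal"):
        self.backend = backend
        self.fallback = fallback
        super().__init__(
            f"backend {backend!r} is not available on PATH; "
            f"use backend={fallback!r} instead"
        )


class ParseError(LegfamError):
    """Malformed input file; reports the offending line where known."""

    def __init__(self, message: str, path: str | None = None,
                 line: int | None = None):
        self.path = path
        self.line = line
        loc = ""
        if path is not None:
            loc = f" [{path}" + (f":{line}" if line is not None else "") + "]"
        super().__init__(message + loc)


class ContractViolation(LegfamError):
    """An operation was called outside its documented precondition."""
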