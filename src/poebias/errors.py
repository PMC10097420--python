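"""Exception hierarchy shared across the package."""


class PoebiasError(Exception):
    """Base class for all package errors."""


class ParseError(PoebiasError):
    """A malformed input row; carries the offending line number."""

    def __init__(self, message: str, path=None, line: int | None = None):
        loc = f"{path}:{line}: " if line is not None else ""
        super().__init__(f"{loc}{message}")
        self.path = path
        self.line = line


class RecordValidationError(PoebiasError):
    """A record violates a structural invariant (e.g. start >= end)."""


class AliasConflictError(PoebiasError):
    """Alias closure tries to merge records on different chromosomes."""


class UndefinedBiasError(PoebiasError):
    """Allelic bias is undefined (zero informative reads); the gene must be
    filtered explicitly rather than silently reported as 50:50."""


class MissingCrossError(PoebiasError):
    """A reciprocal-cross summary was requested with one cross absent.

    The reciprocal mean only cancels strain effects when both crosses are
    present, so a mean of one value is never silently substituted."""


class StrandError(PoebiasError):
    """Operation requires a known strand but the record's strand is unknown."""
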