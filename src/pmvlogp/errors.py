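"""Exception hierarchy shared across the package."""


class PmvLogPError(Exception):
    """Base class for all package-specific errors."""


class FormatError(PmvLogPError):
    """A file could not be parsed: missing columns, malformed values."""


class ValidationError(PmvLogPError):
    """Parsed data violates an invariant of the data model."""


class PhaseError(ValidationError):
    """A record of the wrong phase was passed (e.g. vacuum where solution required)."""


class CoverageError(ValidationError):
    """A molecule is missing from one of the tables required for an operation."""


class DegenerateDataError(PmvLogPError):
    """The training data cannot constrain one of the free parameters."""
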