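"""Exception hierarchy shared across the package."""


class SoilCueError(Exception):
    """Base class for all package errors."""


class InvalidRecordError(SoilCueError):
    """A per-row validation failure; carries the offending field name."""

    def __init__(self, field: str, message: str | None = None):
        self.field = field
        super().__init__(message or f"invalid record: field {field!r}")


class EmptyInputError(SoilCueError):
    """An operation received an empty collection."""


class ConversionError(SoilCueError):
    """A unit conversion received out-of-domain arguments."""


class FitError(SoilCueError):
    """A regression fit could not be performed."""


class ConfigError(SoilCueError):
    """A configuration object violates its invariants."""


class SchemaError(SoilCueError):
    """An input table does not match the expected schema."""
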