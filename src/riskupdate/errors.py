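"""Exception hierarchy shared across the package."""


class RiskUpdateError(Exception):
    """Base class for all package errors."""


class SchemaError(RiskUpdateError):
    """Schema definition or schema/data mismatch problem."""


class ParseError(RiskUpdateError):
    """Malformed value encountered while reading a dataset."""


class FitError(RiskUpdateError):
    """A model fit could not be carried out at all (degenerate input)."""


class DegenerateOutcomeError(FitError):
    """Outcome vector is all events or all non-events."""


class SerializationError(RiskUpdateError):
    """Model file unreadable: bad version, unknown strategy, or corrupt."""


class ConfigError(RiskUpdateError):
    """Invalid population or scenario configuration."""
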