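"""Exception hierarchy shared across the pipeline."""


class TrioExomeError(Exception):
    """Base class for all errors raised by this package."""


class ParseError(TrioExomeError):
    """A file could not be parsed; the message names the offending line."""


class SchemaError(TrioExomeError):
    """A required column or field is missing from an input table."""


class ValidationError(TrioExomeError):
    """Parsed values violate a domain invariant (e.g. alt reads > depth)."""


class ConfigError(TrioExomeError):
    """A configuration value is inconsistent with the data it is applied to."""


class InsufficientDataError(TrioExomeError):
    """Too few observations to compute the requested statistic."""
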