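"""Exception types shared across the pipeline."""


class BotscreenError(Exception):
    """Base class for all package errors."""


class SchemaError(BotscreenError):
    """An input file's header does not match the documented schema."""


class ConfigurationError(BotscreenError):
    """A policy or run configuration is internally inconsistent."""


class ConsistencyError(BotscreenError):
    """Cross-referenced inputs disagree (unknown record id, pv for unregistered record, ...)."""


class UndefinedRateError(BotscreenError, ZeroDivisionError):
    """A rate was requested with a zero denominator."""


class RowParseWarning(UserWarning):
    """A row of an input file could not be parsed or failed validation; it was skipped."""
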