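"""Exception hierarchy.

``ConfigError`` signals a bad run configuration (CLI exit code 1);
``DataError`` and its subclasses signal problems with the input data
(CLI exit code 2).
"""


class ModeshiftError(Exception):
    """Base class for all package errors."""


class ConfigError(ModeshiftError):
    """Invalid configuration: bad parameter values, impossible requests."""


class DataError(ModeshiftError):
    """Invalid or inconsistent input data."""


class SchemaError(DataError):
    """A required column or field is missing from an input table."""


class DuplicateRecordError(DataError):
    """Two records share a (person, commute, timestamp) key."""


class InvalidRecordError(DataError):
    """A record violates a field-level invariant (e.g. negative speed)."""


class InvalidIntervalError(DataError):
    """Speed derivation asked for over a zero-length time interval."""


class MetricsError(DataError):
    """Speed metrics requested for a sequence too short to define them."""
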