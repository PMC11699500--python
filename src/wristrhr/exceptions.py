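"""Exception hierarchy.

ConfigError maps to CLI exit code 2, DataError to exit code 1.
"""


class WristRHRError(Exception):
    """Base class for all package errors."""


class ConfigError(WristRHRError):
    """Invalid configuration value; the message names the offending field."""


class DataError(WristRHRError):
    """Malformed or inconsistent input data; the message locates the record."""


class InsufficientDataError(DataError):
    """Too few observations for the requested statistic."""
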