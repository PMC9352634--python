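"""Typed exceptions shared across the package."""


class SmartlineError(Exception):
    """Base class for all package errors."""


class DataError(SmartlineError):
    """Malformed or inconsistent input data (shapes, signs, NaN/Inf, missing fields)."""


class ConfigError(SmartlineError):
    """Invalid configuration or parameter combination."""


class DegenerateTraceError(SmartlineError):
    """A trace statistic is undefined (constant trace, empty sub-percentile set,
    non-positive baseline)."""
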