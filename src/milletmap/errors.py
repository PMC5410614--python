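"""Typed exceptions used across the package."""


class MilletMapError(Exception):
    """Base class for all package errors."""


class ParseError(MilletMapError):
    """A file token could not be interpreted (names the offending row/column)."""


class ValidationError(MilletMapError):
    """An in-memory object violates one of its invariants."""


class ConfigError(MilletMapError):
    """A configuration value is out of range or inconsistent."""


class AnalysisError(MilletMapError):
    """A statistical operation was asked for on data that cannot support it."""
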