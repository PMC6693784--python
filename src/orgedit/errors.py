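"""Exception hierarchy shared across the package.

``ConfigError`` maps to CLI exit code 2, ``DataError`` (and subclasses) to 3.
"""


class OrgeditError(Exception):
    """Base class for all package errors."""


class ConfigError(OrgeditError):
    """Invalid run configuration (wrong library counts, missing paths, ...)."""


class DataError(OrgeditError):
    """Invalid or inconsistent input data."""


class ValidationError(DataError):
    """A record failed a structural or semantic check."""


class CoordinateError(DataError):
    """A position falls outside the coordinate system it was queried against."""
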