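"""Exception hierarchy.

All recoverable failures raise a subclass of :class:`PathannotError`, so the
CLI can map any library error to a single-line diagnostic and exit code 1.
"""


class PathannotError(Exception):
    """Base class for all errors raised by this package."""


class FormatError(PathannotError):
    """A file does not conform to its declared format (TSV/GMT/XGMML)."""


class ConfigError(PathannotError):
    """Invalid configuration: duplicate approved symbols, unknown icons, ..."""


class InputError(PathannotError):
    """A value passed to an operation violates its preconditions."""
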