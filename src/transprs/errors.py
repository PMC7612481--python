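"""Exception hierarchy shared across the pipeline.

The command-line layer maps these onto process exit codes
(config -> 2, data -> 3, numerical -> 4).
"""


class TransPRSError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(TransPRSError):
    """Invalid or incomplete configuration (bad paths, missing keys)."""


class DataError(TransPRSError, ValueError):
    """Malformed or invariant-violating input data."""


class NumericalError(TransPRSError, RuntimeError):
    """A numerical procedure failed (singular system, separation, ...)."""
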