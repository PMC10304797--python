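"""Exception hierarchy shared across the package.

The CLI maps these onto exit codes: ConfigError -> 2, DataError -> 3,
StageError -> 4.
"""


class PhonaError(Exception):
    """Base class for all package-specific errors."""


class DataError(PhonaError, ValueError):
    """Malformed or contract-violating input data."""


class ConfigError(PhonaError, ValueError):
    """Invalid configuration (bad key, bad value, missing file)."""


class StageError(PhonaError, RuntimeError):
    """A pipeline stage failed after its inputs validated."""
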