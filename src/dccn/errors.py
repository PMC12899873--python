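"""Exception hierarchy.

Exit-code mapping used by the CLI: ConfigError -> 2, DataError -> 3,
numerical failures (ConvergenceError, RankDeficiencyError,
DegenerateInputError) -> 4.
"""


class DccnError(Exception):
    """Base class for all package errors."""


class ConfigError(DccnError):
    """Invalid or inconsistent configuration."""


class DataError(DccnError):
    """Malformed, missing or inconsistent input data."""


class DegenerateInputError(DccnError):
    """Statistical input with no usable variation (e.g. constant ranks)."""


class ConvergenceError(DccnError):
    """An iterative numerical procedure failed to converge."""


class RankDeficiencyError(DccnError):
    """A regression design matrix is rank deficient."""
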