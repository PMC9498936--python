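"""Exception hierarchy shared across the package.

The CLI maps these onto exit codes: ConfigError -> 2, DataError -> 3,
NumericalError -> 4.
"""


class DiveChaosError(Exception):
    """Base class for all package errors."""


class ConfigError(DiveChaosError):
    """Invalid configuration or arguments."""


class DataError(DiveChaosError):
    """Input data violates a contract (gaps, non-monotone time, emptiness)."""


class NumericalError(DiveChaosError):
    """An estimator could not produce a value (no neighbors, no scaling region)."""
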