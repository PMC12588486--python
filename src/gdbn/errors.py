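"""Exception hierarchy shared across the package."""


class GdbnError(Exception):
    """Base class for all package errors."""


class ConfigurationError(GdbnError):
    """Invalid user configuration (unknown fixture, criterion, bad option)."""


class DimensionError(GdbnError):
    """Array shape does not satisfy the operation's contract."""


class NonStationaryError(GdbnError):
    """Simulation refused: the process would diverge in distribution."""


class InsufficientDataError(GdbnError):
    """Not enough rows for the requested fit, fold, or test."""


class SingularFitError(GdbnError):
    """Rank-deficient regression design (duplicated or constant columns)."""
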