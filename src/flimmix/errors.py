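"""Exception types raised by flimmix operations."""


class FlimmixError(ValueError):
    """Base class for flimmix-specific input and state errors."""


class DegenerateMixtureError(FlimmixError):
    """All component weights vanish, so fractions are undefined."""


class DegenerateBasisError(FlimmixError):
    """The least-squares design matrix is rank deficient (e.g. duplicate lifetimes)."""


class ReproducibilityError(FlimmixError):
    """A randomized operation was invoked without a seed."""


class UndefinedStatisticError(FlimmixError):
    """Too few samples (or a constant reference) to define the statistic."""


class BracketError(FlimmixError):
    """The minimal-spacing search bracket does not contain a crossing."""
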