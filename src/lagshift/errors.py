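"""Exception hierarchy shared across the package."""


class LagshiftError(Exception):
    """Base class for all package-specific errors."""


class PlateFormatError(LagshiftError, ValueError):
    """Raised when a plate-reader export violates the declared dialect."""


class PlateLayoutError(LagshiftError, KeyError):
    """Raised when wells in the data and the layout map disagree."""


class ParameterError(LagshiftError, ValueError):
    """Raised for invalid user-supplied parameters (factors, windows, ...)."""


class DataError(LagshiftError, ValueError):
    """Raised when the data are structurally valid but insufficient."""


class UndefinedStatisticError(LagshiftError, ValueError):
    """Raised when a closed-form statistic does not exist for a fit.

    Examples: a lag threshold at or above the carrying capacity, or a
    doubling target 2*N0 that the logistic curve never reaches.
    """
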