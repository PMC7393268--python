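"""Exception hierarchy shared by all analysis modules."""


class BehavtsError(Exception):
    """Base class for all package errors."""


class ConfigurationError(BehavtsError):
    """A required option, column mapping or parameter is missing or invalid."""


class InsufficientDataError(BehavtsError):
    """The input contains too few events/intervals for the requested statistic."""


class InvalidInputError(BehavtsError):
    """The input violates a structural precondition (overlap, codomain, shape)."""


class UndefinedMeasureError(BehavtsError):
    """The requested measure is mathematically undefined for this input
    (e.g. the memory coefficient of a perfectly periodic train)."""


class FitFailureError(BehavtsError):
    """A GLM fit did not converge or the likelihood is degenerate."""
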