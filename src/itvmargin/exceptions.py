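"""Exception hierarchy for :mod:`itvmargin`."""


class ItvMarginError(Exception):
    """Base class for all package-specific errors."""


class InvalidParameterError(ItvMarginError, ValueError):
    """A parameter violates its documented constraints."""


class InsufficientCyclesError(ItvMarginError, ValueError):
    """A trace does not cover enough breathing cycles for phase sorting."""


class MissingReferenceError(ItvMarginError, KeyError):
    """The reference fraction (fraction 1) is absent for a patient."""


class InsufficientDataError(ItvMarginError, ValueError):
    """Too few rows, patients or pairs to compute the requested statistic."""


class UndefinedStatisticError(ItvMarginError, ValueError):
    """The requested statistic is undefined for this input (e.g. zero variance)."""


class SchemaError(ItvMarginError, ValueError):
    """A cohort table violates the documented CSV schema."""
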