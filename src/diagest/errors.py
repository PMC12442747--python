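"""Exception hierarchy.

Everything raised on purpose by this package derives from :class:`DiagestError`,
so callers can catch one type at the CLI boundary.
"""


class DiagestError(Exception):
    """Base class for all package errors."""


class SchemaError(DiagestError):
    """A required column or configuration key is missing or misnamed."""


class ParseError(DiagestError):
    """A data value is outside the allowed vocabulary."""


class SpecValidationError(DiagestError):
    """An estimand specification violates its own schema rules."""


class StrategyApplicabilityError(DiagestError):
    """A strategy cannot be applied to a record as configured.

    The canonical case: an interfering event left no test decision and the
    diagnostic-policy strategy has no imputation rule configured.
    """


class EventResolutionError(DiagestError):
    """Multiple occurred events cannot be reduced to a single governing one."""


class UndefinedEstimateError(DiagestError):
    """An accuracy measure has an empty denominator."""


class ImputationError(DiagestError):
    """An imputation rule is missing, misconfigured, or produced no result."""


class UnpairedDesignError(DiagestError):
    """An operation requiring a paired design was called on unpaired data."""
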