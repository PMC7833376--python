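"""Exception hierarchy for slncalc."""


class SlncalcError(Exception):
    """Base class for all slncalc errors."""


class CohortSchemaError(SlncalcError):
    """A cohort file is missing required columns or has a malformed header."""


class RecordValidationError(SlncalcError):
    """A patient record violates a field invariant.

    Carries the offending row index (0-based data row, if known) and field name.
    """

    def __init__(self, message: str, row: int | None = None, field: str | None = None):
        super().__init__(message)
        self.row = row
        self.field = field


class ConfigurationError(SlncalcError):
    """A factor scheme, parameter set, or experiment config is inconsistent."""


class DegenerateCohortError(SlncalcError):
    """A cohort or stratum has prevalence 0 or 1 where a finite fit requires both classes."""


class ModelOverflowError(SlncalcError):
    """The risk-model exponent overflowed; the probability would silently round to 1."""


class SolverError(SlncalcError):
    """The root finder failed to bracket or converge within its iteration budget."""
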