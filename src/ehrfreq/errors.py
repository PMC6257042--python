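"""Exception hierarchy shared across the package."""


class EhrFreqError(Exception):
    """Base class for all package errors."""


class SchemaError(EhrFreqError):
    """A file is missing a required column or has an unexpected header."""


class IntegrityError(EhrFreqError):
    """Input data violates a uniqueness or consistency constraint."""


class RowError(EhrFreqError):
    """A specific data row could not be parsed (carries the row number)."""


class UndefinedStatisticError(EhrFreqError):
    """A statistic is undefined for the given inputs (e.g. zero denominator)."""


class InconsistentCountsError(EhrFreqError):
    """Counts imply a negative contingency cell or violate a bound."""


class InfeasibleSpecError(EhrFreqError):
    """A synthetic-cohort specification cannot be realised."""


class NotFoundError(EhrFreqError):
    """A requested concept or dataset does not exist."""
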