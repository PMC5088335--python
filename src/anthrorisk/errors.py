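"""Exception hierarchy.

Every error raised by the package derives from :class:`AnthroriskError` so
callers (and the CLI) can distinguish domain failures from programming bugs.
"""


class AnthroriskError(Exception):
    """Base class for all package errors."""


class DomainError(AnthroriskError, ValueError):
    """An input value is outside its physical/mathematical domain."""


class SchemaError(AnthroriskError, ValueError):
    """A table is missing required columns or has an invalid layout."""


class InsufficientDataError(AnthroriskError, ValueError):
    """Too few records (or events) to perform the requested fit."""


class SingularFitError(AnthroriskError, ValueError):
    """Degenerate design matrix (e.g. a constant regressor)."""


class ConvergenceError(AnthroriskError, RuntimeError):
    """Iterative optimization failed to converge."""


class OutOfReferenceError(AnthroriskError, ValueError):
    """A subject's age falls outside the reference table coverage."""


class DegenerateReferenceError(AnthroriskError, ValueError):
    """A reference cell has zero/undefined SD and cannot be used for z-scoring."""


class UnknownIndexError(AnthroriskError, KeyError):
    """An index name is not one of the supported anthropometric indices."""


class MissingReferenceError(AnthroriskError, ValueError):
    """An empirical operation was requested without an attached reference cohort."""


class ComparabilityError(AnthroriskError, ValueError):
    """Model fits being compared were not computed on the same cohort/outcome."""


class UndefinedConcordanceError(AnthroriskError, ValueError):
    """No comparable pairs exist, so concordance is undefined."""


class UndefinedLikelihoodError(AnthroriskError, ValueError):
    """The partial likelihood is undefined (no events)."""


class ScoringError(AnthroriskError, ValueError):
    """A subject cannot be scored (missing fields, degenerate model)."""
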