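"""Exception hierarchy.

Everything user-facing derives from :class:`ValidationError` so that callers
(and the CLI) can distinguish bad input from genuine bugs.
"""


class ValidationError(ValueError):
    """Base class for invalid input or configuration."""


class TreeFormatError(ValidationError):
    """A tree file could not be parsed."""


class EnsembleMismatchError(ValidationError):
    """Trees in an ensemble do not share one identical tip-label set."""


class DegenerateInputError(ValidationError):
    """Too few species/tips for the requested computation."""


class UnknownSpeciesError(ValidationError):
    """A species label is absent from the tree, matrix or table addressed."""


class StandardizationError(ValidationError):
    """A quantitative trait column cannot be mean-standardized."""


class ImputationError(ValidationError):
    """No computable pairwise distance exists to impute from."""


class UndefinedCorrelationError(ValidationError):
    """A rank correlation is undefined (constant or too-short vectors)."""


class DataError(ValidationError):
    """Inconsistent survey data (conflicting coordinates, zero totals...)."""


class ConfigError(ValidationError):
    """Invalid configuration (synonym cycles, bad thresholds...)."""
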