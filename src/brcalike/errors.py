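"""Exception hierarchy shared across the package."""


class BrcalikeError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(BrcalikeError):
    """Input data violates a documented contract (vocabulary, range, shape)."""


class InvalidConfigError(BrcalikeError):
    """A configuration object is internally inconsistent."""


class InvalidInputError(BrcalikeError):
    """A value passed to an operation is outside its domain."""


class FitError(BrcalikeError):
    """A model fit could not be performed (too few points, no support)."""


class DegenerateFitError(FitError):
    """The data admit no informative fit (e.g. zero variance)."""


class DataIntegrityError(BrcalikeError):
    """Cross-referenced inputs disagree (e.g. reference context mismatch)."""


class StratificationError(BrcalikeError):
    """Cross-validation folds cannot contain both classes."""


class UndefinedStatisticError(BrcalikeError):
    """The requested statistic is undefined for the given group sizes."""
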