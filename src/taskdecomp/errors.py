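"""Exception hierarchy.

Every error raised by the package derives from :class:`TaskDecompError`, so
callers can catch domain failures without masking programming errors.
"""


class TaskDecompError(Exception):
    """Base class for all taskdecomp errors."""


class FormatError(TaskDecompError):
    """A file does not conform to the expected tabular/JSON layout."""


class StructuralError(TaskDecompError):
    """Trial collection is internally inconsistent (joints, missing files...)."""


class CoverageError(TaskDecompError):
    """A trial does not span the requested analysis window."""


class ParameterError(TaskDecompError):
    """An argument is outside its valid domain."""


class DataError(TaskDecompError):
    """Input data contain non-finite or otherwise unusable values."""


class NoReleaseError(TaskDecompError):
    """Ball-finger distance never exceeds the release threshold."""


class DegenerateDirectionError(TaskDecompError):
    """The classifier weight vector is (numerically) zero; the projection is undefined."""


class InsufficientDataError(TaskDecompError):
    """Too few trials/subjects for the requested statistic."""


class StratificationError(TaskDecompError):
    """Cross-validation folds cannot be stratified with both classes present."""


class IncompleteDesignError(TaskDecompError):
    """A within-subject factorial design is missing cells."""
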