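"""Exception hierarchy for the morphometry prediction pipeline.

Every error raised on bad user input derives from :class:`MorphPredError`,
so callers (and the CLI) can catch one base class.
"""


class MorphPredError(Exception):
    """Base class for all package-specific errors."""


class SchemaMismatchError(MorphPredError):
    """Feature columns do not match the expected region schema."""

    def __init__(self, message, missing=(), extra=()):
        super().__init__(message)
        self.missing = tuple(missing)
        self.extra = tuple(extra)


class TableParseError(MorphPredError):
    """A delimited feature/subject table could not be parsed.

    Carries the offending row/column coordinates when known.
    """

    def __init__(self, message, row=None, column=None):
        super().__init__(message)
        self.row = row
        self.column = column


class DuplicateSubjectError(MorphPredError):
    """The same subject id appears more than once."""


class AlignmentError(MorphPredError):
    """Two tables do not contain the same subject set."""

    def __init__(self, message, only_first=(), only_second=()):
        super().__init__(message)
        self.only_first = tuple(only_first)
        self.only_second = tuple(only_second)


class MissingRegionError(MorphPredError):
    """A structure required by the schema is absent from a stats file."""


class StatsParseError(MorphPredError):
    """A FreeSurfer-style regional stats file has a malformed row."""

    def __init__(self, message, line_number=None):
        super().__init__(message)
        self.line_number = line_number


class LabelingError(MorphPredError):
    """A subject cannot be assigned a responder label."""


class CohortValidationError(MorphPredError):
    """Subject records are internally inconsistent (flow status vs data)."""


class SpecError(MorphPredError):
    """A synthetic-cohort specification is infeasible or invalid."""


class ConfigError(MorphPredError):
    """A model or run configuration violates its invariants."""


class DivergenceError(MorphPredError):
    """Network training produced a non-finite loss."""

    def __init__(self, message, layer=None, epoch=None):
        super().__init__(message)
        self.layer = layer
        self.epoch = epoch


class EvaluationError(MorphPredError):
    """Cross-validation or metric computation received invalid inputs."""
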