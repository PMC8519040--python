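"""Exception hierarchy for isomilk."""


class IsomilkError(Exception):
    """Base class for all isomilk errors."""


class InvalidMeasurementError(IsomilkError, ValueError):
    """A delta value or uncertainty is non-finite or physically impossible."""


class InvalidDateError(IsomilkError, ValueError):
    """A calendar date cannot be mapped to a non-leap day number (e.g. 29 February)."""


class InvalidRecordError(IsomilkError, ValueError):
    """A sample record is missing fields required by the requested operation."""


class SingularFitError(IsomilkError, ValueError):
    """The regression design matrix is rank deficient (degenerate predictors)."""


class WindowTooSmallError(IsomilkError, ValueError):
    """A LOESS span leaves fewer than three points in the local window."""


class InsufficientDataError(IsomilkError, ValueError):
    """Too few usable observations for the requested fit or statistic."""


class IncompleteDesignError(IsomilkError, ValueError):
    """The two-way ANOVA layout has missing cells."""


class InvalidConfigError(IsomilkError, ValueError):
    """A simulation or run configuration is inconsistent or has unknown keys."""


class SchemaError(IsomilkError, ValueError):
    """An input file is missing mandatory columns."""
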