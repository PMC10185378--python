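"""Exception hierarchy shared across the pipeline."""


class ActionSpaceError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(ActionSpaceError):
    """Input file does not expose the required columns."""


class ValidationError(ActionSpaceError):
    """Record-level contract violation (e.g. a rating outside 1-9)."""


class MissingDataError(ActionSpaceError):
    """A required (action, characteristic) cell has no ratings."""


class DegenerateDataError(ActionSpaceError):
    """Input is degenerate for the requested statistic (constant column,
    singular correlation matrix, zero between-subject variance, ...)."""


class ConvergenceError(ActionSpaceError):
    """An iterative fit failed to converge after all allowed restarts."""
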