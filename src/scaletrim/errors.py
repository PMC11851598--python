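"""Exception hierarchy.

Every failure mode raises a subclass of :class:`ScaleTrimError` so callers
can catch toolkit errors without masking programming mistakes.
"""


class ScaleTrimError(Exception):
    """Base class for all scaletrim errors."""


class SchemaError(ScaleTrimError):
    """A file or table is missing a required field/column, or labels mismatch."""


class ValidationError(ScaleTrimError):
    """An object violates a structural invariant (duplicate ids, empty text...)."""


class RangeError(ScaleTrimError):
    """An ordinal response value lies outside 1..K."""


class StateError(ScaleTrimError):
    """An operation was applied in the wrong state (e.g. double reverse-scoring)."""


class ParameterError(ScaleTrimError):
    """A caller-supplied parameter is infeasible (k too large, bad rates...)."""


class ConfigError(ScaleTrimError):
    """A configuration entry is unknown or malformed."""


class BackendError(ScaleTrimError):
    """An embedding backend is unavailable or failed."""


class EstimationError(ScaleTrimError):
    """An estimator could not run on the supplied data."""


class ConvergenceError(EstimationError):
    """An iterative estimator hit its iteration cap.

    Carries the last iterate and the iteration trace for diagnosis.
    """

    def __init__(self, message, last_iterate=None, trace=None):
        super().__init__(message)
        self.last_iterate = last_iterate
        self.trace = trace


class UndefinedStatisticError(ScaleTrimError):
    """A statistic is undefined for the given input (zero vector, zero variance...)."""
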