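"""Exception taxonomy shared across the pipeline stages."""


class StrokeClustError(Exception):
    """Base class for all package errors."""


class ConfigurationError(StrokeClustError, ValueError):
    """A configuration object violates one of its invariants."""


class InputError(StrokeClustError, ValueError):
    """Caller-supplied data is malformed (wrong shape, length, range)."""


class DataError(StrokeClustError, ValueError):
    """Data is structurally valid but unusable (non-finite, degenerate)."""


class NumericError(StrokeClustError, ArithmeticError):
    """An iterative computation produced non-finite intermediates."""


class LabelingError(StrokeClustError, ValueError):
    """Severity/reference labeling failed (unknown group, bad score)."""


class EvaluationError(StrokeClustError, ValueError):
    """Evaluation preconditions violated (e.g. an empty cluster)."""
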