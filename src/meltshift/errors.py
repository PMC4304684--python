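"""Exception hierarchy for meltshift."""


class MeltshiftError(Exception):
    """Base class for all meltshift errors."""


class ValidationError(MeltshiftError, ValueError):
    """Raised when input data violate a documented invariant."""


class AnalysisError(MeltshiftError, RuntimeError):
    """Raised when an analysis step cannot proceed (e.g. no usable reference)."""


class UnsupportedConditionError(MeltshiftError, ValueError):
    """Raised when a condition lacks the data a computation requires."""
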