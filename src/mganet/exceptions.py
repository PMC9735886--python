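"""Exception hierarchy.

All library errors derive from :class:`MganetError` so callers can catch one
base class; the subclasses mirror the failure categories used throughout the
API contracts (bad argument values, invalid data, numeric blow-ups, training
divergence).
"""


class MganetError(Exception):
    """Base class for all mganet errors."""


class ParameterError(MganetError, ValueError):
    """An argument value is outside its documented domain."""


class ValidationError(MganetError, ValueError):
    """Input data violates a structural invariant."""


class NumericError(MganetError, ArithmeticError):
    """A computation produced non-finite intermediates."""


class TrainingError(MganetError, RuntimeError):
    """Optimization diverged or could not proceed."""
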