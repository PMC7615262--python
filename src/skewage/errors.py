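"""Typed exceptions.

Errors are deliberately fine-grained so the training controller can
distinguish a collapsed model (constant predictions, undefined correlation)
from genuine misconfiguration or numeric failure.
"""


class SkewageError(Exception):
    """Base class for all package errors."""


class ConfigurationError(SkewageError, ValueError):
    """Invalid configuration (degenerate age range, bad hyperparameter, ...)."""


class InputError(SkewageError, ValueError):
    """Invalid runtime input (non-finite value, length mismatch, empty batch)."""


class UndefinedCorrelationError(SkewageError, ValueError):
    """Correlation is undefined because one of the variables is constant."""


class FitError(SkewageError, ValueError):
    """A regression fit could not be performed (too few points, constant x)."""


class DegenerateSlopeError(SkewageError, ValueError):
    """Fitted slope too close to zero to invert safely."""


class StratificationError(SkewageError, ValueError):
    """An age bin is too small to split at the requested fractions."""


class TrainingError(SkewageError, RuntimeError):
    """Training failed (e.g. persistently undefined validation correlation)."""
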