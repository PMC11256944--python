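"""Exception hierarchy for qmsdr.

All errors derive from :class:`QmsError` so callers can catch package
failures with a single except clause.
"""


class QmsError(Exception):
    """Base class for all qmsdr errors."""


class FormatError(QmsError):
    """A file does not conform to the expected tabular dialect."""


class ValidationError(QmsError):
    """Input data violates a domain invariant (e.g. negative AUDRC)."""


class ConfigError(QmsError):
    """A configuration object is internally inconsistent."""


class DimensionError(QmsError):
    """Array shapes do not match the model contract."""


class TrainingError(QmsError):
    """Model optimisation failed (e.g. NaN loss)."""


class IntegrityError(QmsError):
    """A cross-validation partition is leaky or overlapping."""


class EvaluationError(QmsError):
    """A statistic is undefined for the given inputs."""


class StateError(QmsError):
    """An operation was called on a model in the wrong mode."""
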