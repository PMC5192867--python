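"""Exception hierarchy.

Every error raised on a contract violation derives from :class:`SasimError`
so callers can catch the whole family in one clause.
"""


class SasimError(Exception):
    """Base class for all package-specific errors."""


class DuplicateFactor(SasimError):
    """A factor with this name is already present in the table."""


class InvalidRange(SasimError):
    """Factor range is degenerate or inverted (requires lower < upper)."""


class EmptyFactorTable(SasimError):
    """A sampling design was requested over zero factors."""


class InvalidLevels(SasimError):
    """Level count incompatible with the requested design or step mode."""


class InvalidSampleSize(SasimError):
    """Base sample size too small for the requested estimator."""


class UnknownParameter(SasimError):
    """A factor name is not among the model's declared parameters."""


class ShapeError(SasimError):
    """Array / table dimensions do not match the design they refer to."""


class ModelExecutionError(SasimError):
    """The model raised during setup or run; carries the run context."""


class ObjectiveContractError(SasimError):
    """The objective function returned inconsistent names or non-scalars."""


class DegenerateVariance(SasimError):
    """Output variance is zero; variance-based indices are undefined."""


class UndefinedCV(SasimError):
    """Coefficient of variation undefined (sample mean is zero)."""


class InsufficientSamples(SasimError):
    """Fewer samples than the statistic requires."""


class DegenerateReference(SasimError):
    """Reference series is constant; range-normalised error undefined."""


class ParameterError(SasimError):
    """A simulator received an invalid parameter value."""


class ConfigError(SasimError):
    """The run configuration file is missing, malformed or incomplete."""
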