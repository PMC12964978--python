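"""Exception hierarchy for the pneumocea pipeline.

Every stage raises a subclass of :class:`PneumoceaError` so callers (and the
CLI) can distinguish configuration mistakes from numerical/degeneracy
failures without string-matching messages.
"""


class PneumoceaError(Exception):
    """Base class for all package errors."""


class ConfigurationError(PneumoceaError):
    """Invalid configuration value (probability vector, hazard, caliper, ...)."""


class EmptyInputError(PneumoceaError):
    """An operation that requires data received an empty collection."""


class SchemaError(PneumoceaError):
    """Tabular input does not match the expected cohort schema."""


class SeparationError(PneumoceaError):
    """Complete or quasi-complete separation in the propensity model."""


class CollinearityError(PneumoceaError):
    """Rank-deficient design matrix in the propensity model."""


class DegenerateVarianceError(PneumoceaError):
    """Zero pooled variance with a non-zero mean difference in an SMD."""


class DegenerateInputError(PneumoceaError):
    """Statistical test input carries no usable information (e.g. no events)."""


class ConvergenceError(PneumoceaError):
    """An iterative fit diverged or failed to converge (monotone likelihood)."""


class PairingError(PneumoceaError):
    """Matched-cohort operation received arms of unequal size."""
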