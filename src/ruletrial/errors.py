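"""Exception hierarchy for ruletrial.

Every error raised deliberately by the package derives from
:class:`RuleTrialError`, so callers can distinguish modelling failures
(positivity, separation) from programming errors.
"""


class RuleTrialError(Exception):
    """Base class for all ruletrial errors."""


class ConfigurationError(RuleTrialError):
    """Invalid user-supplied configuration (bad family, bad fraction, ...)."""


class SchemaError(RuleTrialError):
    """A required column or field is missing from an input table."""


class AlignmentError(RuleTrialError):
    """Two per-subject vectors/tables that must be aligned have different lengths."""


class DataError(RuleTrialError):
    """Input data violates an invariant (negative offsets, non-binary outcome, ...)."""


class FittingError(RuleTrialError):
    """A regression model failed to fit (separation, rank deficiency, non-convergence)."""


class PositivityError(RuleTrialError):
    """A stratum lacks subjects on a treatment needed for g-computation."""

    def __init__(self, message: str, stratum: str | None = None):
        super().__init__(message)
        self.stratum = stratum


class EstimationError(RuleTrialError):
    """An estimator received degenerate input (e.g. an empty cohort)."""


class OptimizationError(RuleTrialError):
    """No candidate decision rule could be evaluated."""


class InferenceError(RuleTrialError):
    """Bootstrap inference failed (too many replicates lost positivity)."""
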