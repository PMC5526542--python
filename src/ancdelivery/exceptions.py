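"""Exception hierarchy for configuration, data and estimation failures."""


class AncDeliveryError(Exception):
    """Base class for all package errors."""


class ConfigurationError(AncDeliveryError, ValueError):
    """Invalid simulation or analysis configuration."""


class DataError(AncDeliveryError, ValueError):
    """Input data violate a precondition (coding, range, missingness)."""


class DegenerateInputError(AncDeliveryError, ValueError):
    """Input has no usable variation (constant scores, zero variance)."""


class EstimationInputError(AncDeliveryError, ValueError):
    """Design matrix unsuitable for estimation (collinearity, rank)."""


class SeparationError(AncDeliveryError, RuntimeError):
    """Perfect separation: the probit MLE does not exist."""


class ConvergenceError(AncDeliveryError, RuntimeError):
    """Optimizer failed to converge to an interior optimum."""


class ExclusionRestrictionError(AncDeliveryError, ValueError):
    """Instrument appears in the outcome equation design."""


class InferenceError(AncDeliveryError, RuntimeError):
    """Standard errors unavailable (singular observed information)."""


class PipelineError(AncDeliveryError, RuntimeError):
    """One or more model blocks failed in an end-to-end run."""

    def __init__(self, message, report=None):
        super().__init__(message)
        self.report = report
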