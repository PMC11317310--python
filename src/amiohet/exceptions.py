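"""Package exception hierarchy."""


class AmiohetError(Exception):
    """Base class for package errors."""


class ConfigurationError(AmiohetError, ValueError):
    """Invalid configuration: bad dimensions, probabilities, fold counts."""


class ValidationError(AmiohetError, ValueError):
    """Input data violates the data dictionary or contains invalid values."""


class EstimationError(AmiohetError, RuntimeError):
    """A model fit cannot proceed (e.g. a single-arm training set)."""


class DegenerateOutcomeError(EstimationError):
    """Outcome vector is constant, so a logistic model is unidentifiable."""
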