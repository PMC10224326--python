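"""Exception hierarchy shared across the package."""


class CCIKitError(Exception):
    """Base class for all package errors."""


class ConfigurationError(CCIKitError):
    """A configuration value is invalid; the message names the field."""


class DataError(CCIKitError):
    """Input records violate an invariant; the message identifies them."""


class SamplingError(CCIKitError):
    """A sample request cannot be satisfied by the population."""


class EstimationError(CCIKitError):
    """An estimator received an empty or degenerate input."""


class TestError(CCIKitError):
    """A hypothesis test cannot be computed on the given data."""


class FitError(CCIKitError):
    """Model fitting failed; carries the last iterate where available."""

    def __init__(self, message, last_params=None):
        super().__init__(message)
        self.last_params = last_params


class DomainError(CCIKitError):
    """A value lies outside the mathematical domain of an operation."""
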