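"""Exception hierarchy shared across the pipeline stages."""


class VPHIError(Exception):
    """Base class for all package errors."""


class ConfigurationError(VPHIError, ValueError):
    """A config file, column mapping or option is malformed or incomplete."""


class ValidationError(VPHIError, ValueError):
    """Input records violate the survey schema (names the offending rows)."""


class DomainError(VPHIError, ValueError):
    """A scalar argument is outside its mathematical domain."""


class DesignError(VPHIError, ValueError):
    """A design matrix is rank deficient or mis-shaped."""


class EstimationError(VPHIError, RuntimeError):
    """An estimation stage cannot produce a fit (separation, no variation...)."""


class InferenceError(VPHIError, RuntimeError):
    """Bootstrap / testing stage failed (too many broken replicates...)."""
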