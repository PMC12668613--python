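"""Exception hierarchy for xenoeq."""


class XenoeqError(Exception):
    """Base class for all package errors."""


class ConfigurationError(XenoeqError):
    """Invalid generator or pipeline configuration."""


class FormatError(XenoeqError):
    """On-disk registry does not match the documented schema."""


class EstimationError(XenoeqError):
    """A survival or logistic fit cannot be carried out (e.g. zero events)."""


class MissingCovariateError(XenoeqError):
    """A prediction was requested for a patient lacking a model covariate."""


class UnsupportedBackendError(XenoeqError):
    """The requested operation is not defined for this model backend."""


class DegenerateConditioningError(XenoeqError):
    """Conditioning a survival curve on a time where survival is zero."""


class RelistEstimationError(EstimationError):
    """No graft failures in the requested stratum; fall back to the parent cohort."""


class EmptyDonorPoolError(XenoeqError):
    """No blood-compatible donor available for the requested patient."""
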