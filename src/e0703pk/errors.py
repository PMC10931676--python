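"""Exception types shared across the package."""


class E0703PKError(Exception):
    """Base class for package errors."""


class InvalidProfileError(E0703PKError):
    """A concentration-time profile violates its invariants."""


class InvalidAssayError(E0703PKError):
    """An in vitro assay record is unusable (singular fit, zero donor, ...)."""


class NotEstimableError(E0703PKError):
    """A derived quantity (terminal slope, bioavailability) cannot be estimated."""


class ConfigurationError(E0703PKError):
    """Required metadata, physiology constants or model inputs are missing."""


class PhysiologyValidationError(ConfigurationError):
    """Whole-body physiology violates flow/volume closure."""
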