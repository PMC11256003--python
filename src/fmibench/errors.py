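"""Exception hierarchy for the fmibench pipeline."""


class FmibenchError(Exception):
    """Base class for all fmibench errors."""


class ConfigError(FmibenchError):
    """Invalid configuration value (bit depth, preset name, ...)."""


class GeometryError(FmibenchError):
    """Geometry falls outside the image frame or shapes mismatch."""


class MaskError(FmibenchError):
    """A ROI mask is empty or violates the disjointness contract."""


class FormatError(FmibenchError):
    """Unsupported image file format or dtype."""


class DegenerateHistogramError(FmibenchError):
    """Thresholding requested on a constant (single-valued) image."""


class RegistrationError(FmibenchError):
    """Too few circles to register the design template."""


class RegistrationQualityError(RegistrationError):
    """Template registration converged with an unacceptable residual."""


class InvalidTransformError(FmibenchError):
    """Similarity transform with a non-positive scale."""


class DomainError(FmibenchError, ValueError):
    """Metric evaluated outside its mathematical domain."""


class UndefinedNoiseError(DomainError):
    """SNR denominator (a standard deviation) is zero."""
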