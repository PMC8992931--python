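"""Exception hierarchy for stereomu."""


class StereoMUError(Exception):
    """Base class for all stereomu errors."""


class InputError(StereoMUError, ValueError):
    """Invalid value passed to a computation (negative depth, zero diameter, ...)."""


class FitError(StereoMUError):
    """Curve fitting failed or did not converge."""


class ConfigurationError(StereoMUError):
    """Commissioning/archive configuration is incomplete or inconsistent."""


class DicomError(StereoMUError):
    """A DICOM object is missing, malformed, or unsupported."""


class GeometryError(StereoMUError):
    """Ray tracing failed (isocenter outside body, insufficient CT coverage, ...)."""


class ComputationError(StereoMUError):
    """An MU computation produced a non-physical intermediate (e.g. TMR <= 0)."""
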