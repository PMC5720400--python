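"""Exception hierarchy for the bench."""


class SlitCbctError(Exception):
    """Base class for all package errors."""


class InvalidSpecError(SlitCbctError, ValueError):
    """A geometry or collimator specification violates an invariant."""


class ConfigurationError(SlitCbctError, ValueError):
    """A configuration block is missing or inconsistent."""


class CalibrationError(SlitCbctError, RuntimeError):
    """Scatter-scale calibration could not be performed (e.g. zero primary)."""


class InsufficientSamplesError(SlitCbctError, ValueError):
    """Fewer than two closed septa project onto the detector."""


class PairingError(SlitCbctError, ValueError):
    """Two half-acquisitions do not belong to the same gantry angle set."""


class UnsupportedOrbitError(SlitCbctError, ValueError):
    """Projection angles are not a uniformly sampled full circular orbit."""


class RegionError(SlitCbctError, ValueError):
    """An evaluation region is empty after rasterization."""


class UndefinedContrastError(SlitCbctError, ZeroDivisionError):
    """Contrast ratio undefined because the surround mean is zero."""
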