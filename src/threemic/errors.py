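"""Exception hierarchy shared across the package."""


class ThreeMICError(Exception):
    """Base class for all package errors."""


class SpecError(ThreeMICError, ValueError):
    """Invalid generator or simulation specification."""


class ConfigError(ThreeMICError, ValueError):
    """Invalid or incomplete scenario / simulation configuration."""


class FormatError(ThreeMICError, ValueError):
    """Malformed input file (CSV schema, TIFF dtype, ...)."""


class GeometryError(ThreeMICError, ValueError):
    """Degenerate geometry (too few points, collinear sets, ...)."""


class ObjectNotFoundError(ThreeMICError, KeyError):
    """Requested label missing from a mask, or too small to measure."""


class SignalError(ThreeMICError, ValueError):
    """Degenerate fluorescence signal (zero/negative denominator or source)."""


class FitError(ThreeMICError, ValueError):
    """Regression or power-law fit cannot be performed."""


class TrackIntegrityError(ThreeMICError, ValueError):
    """A track violates its ordering/sampling contract."""


class InsufficientDataError(ThreeMICError, ValueError):
    """Not enough observations for the requested statistic."""


class CalibrationError(ThreeMICError, ValueError):
    """Calibration anchors violate monotonicity requirements."""
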