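"""Exception hierarchy shared across the package."""


class StvqtError(Exception):
    """Base class for all package-specific errors."""


class InvalidParameterError(StvqtError, ValueError):
    """A configuration or morphology parameter violates its contract."""


class CalibrationError(StvqtError, ValueError):
    """A requested short-term-variability target cannot be calibrated."""


class RangeError(StvqtError, ValueError):
    """A time, index or step falls outside the valid range."""


class UnsupportedFormatError(StvqtError, ValueError):
    """Unknown or unavailable record serialization format."""


class NoBeatsError(StvqtError):
    """No QRS complexes could be detected in the signal."""


class InsufficientBeatsError(StvqtError):
    """Too few usable beats to build an averaged template."""


class InsufficientDataError(StvqtError):
    """Too few valid observations for the requested statistic."""


class TEndNotFoundError(StvqtError):
    """The tangent method found no baseline crossing after the T peak."""


class AnnotationError(StvqtError):
    """Template fiducials violate their ordering invariant."""


class ConfigurationError(StvqtError):
    """Inconsistent inputs (fs mismatch, missing event, missing field...)."""
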