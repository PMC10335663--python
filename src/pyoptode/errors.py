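"""Exception and warning hierarchy.

All package-raised errors derive from :class:`OptodeError` so callers can
catch the whole family; input-validation errors additionally derive from
``ValueError`` so they behave sensibly in generic code.
"""


class OptodeError(Exception):
    """Base class for all errors raised by this package."""


class InputError(OptodeError, ValueError):
    """Malformed or insufficient input (wrong shape, too few points, ...)."""


class DomainError(OptodeError, ValueError):
    """A physical quantity outside its valid domain (negative C, T out of range)."""


class GeometryError(OptodeError, ValueError):
    """An ROI that does not fit inside the image it refers to."""


class RenderError(OptodeError, ValueError):
    """A synthetic frame whose requested intensities exceed the sensor range."""


class DegenerateCalibrationError(OptodeError, ValueError):
    """A calibration that cannot be inverted (Ksv == 0)."""


class OutOfRangeError(OptodeError, ValueError):
    """A measured ratio below the nonquenchable floor alpha*R0."""


class MetrologyError(OptodeError, ValueError):
    """Detection-limit computation with a zero or undefined slope."""


class NormalizationError(OptodeError, ValueError):
    """Normalisation of a list with no positive entries."""


class FitError(OptodeError, RuntimeError):
    """Nonlinear fit failure; carries the initialisation and residuals seen."""

    def __init__(self, message, init=None, residuals=None):
        super().__init__(message)
        self.init = init
        self.residuals = residuals


class SuperSaturationWarning(UserWarning):
    """Measured ratio above R0: indicated oxygen clamped to zero."""


class ExtrapolationWarning(UserWarning):
    """Salinity outside the calibrated 0-3.5 % m/v range."""


class MaskFractionWarning(UserWarning):
    """Outlier masking removed more than the advisory fraction of points."""


class IdentifiabilityWarning(UserWarning):
    """A fit whose data carry almost no information about a parameter."""
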