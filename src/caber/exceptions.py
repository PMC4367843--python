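"""Exception hierarchy.

All package errors derive from :class:`CaberError` so callers can catch one
base class; subclasses distinguish configuration, imaging and fitting
failures (the CLI maps them to distinct exit codes).
"""


class CaberError(Exception):
    """Base class for all errors raised by this package."""


class InvalidParameterError(CaberError, ValueError):
    """A physical parameter violates its invariant (e.g. negative viscosity)."""


class InvalidGeometryError(CaberError, ValueError):
    """A geometric quantity is inconsistent (e.g. D0 <= 0, g_f < g_0)."""


class SingularCorrectionError(InvalidParameterError):
    """Newtonian correction factor X <= 0.5 makes Eq.-of-motion singular."""


class CalibrationError(CaberError):
    """Pixel-scale calibration failed (no platen silhouette found)."""


class BinarizationError(CaberError):
    """Automatic thresholding impossible (e.g. constant frame)."""


class MotionStopNotFoundError(CaberError):
    """The platen gap never settled within tolerance of the final gap."""


class PrematureBreakupError(CaberError):
    """Filament already broken when the platens stopped moving."""


class NonThinningError(CaberError):
    """Trace diameter does not decrease; thinning fit is meaningless."""


class MinPointsError(CaberError):
    """Too few usable points for the requested regression."""


class UndefinedRSquaredError(CaberError):
    """R^2 undefined because the observed values have zero variance."""
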