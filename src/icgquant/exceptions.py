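"""Exception and warning types for the ICG perfusion analysis pipeline."""


class IcgQuantError(Exception):
    """Base class for all package errors."""


class InvalidSpecificationError(IcgQuantError, ValueError):
    """A generator or analysis specification is internally inconsistent."""


class CurveFormatError(IcgQuantError, ValueError):
    """A time-intensity curve or frame stack violates the format contract."""


class InvalidRoiError(IcgQuantError, ValueError):
    """An ROI mask is empty or does not match the frame geometry."""


class NoPerfusionError(IcgQuantError, RuntimeError):
    """No sustained fluorescence increase was detected within the analysis window.

    Clinical analogue: the bowel segment shows no dye inflow within the
    observation period (the intraoperative protocol caps observation at
    a few minutes before declaring absent perfusion).
    """


class InternalConsistencyError(IcgQuantError, RuntimeError):
    """A pathological curve produced mutually inconsistent landmarks."""


class UndefinedStatisticError(IcgQuantError, ValueError):
    """A requested statistic has no defined value (e.g. zero denominator)."""


class PeakNotReachedWarning(UserWarning):
    """The curve is still rising at the end of the analysis window.

    T_MAX is censored at the window end and the result flagged; classification
    treats a censored time-to-maximum as slow perfusion.
    """
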