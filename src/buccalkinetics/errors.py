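"""Exception hierarchy shared by all analysis modules."""


class BuccalKineticsError(Exception):
    """Base class for all package-specific errors."""


class InvalidInputError(BuccalKineticsError, ValueError):
    """Raised when input data violate a documented precondition."""


class DegenerateCurveError(BuccalKineticsError):
    """Raised when a calibration curve or fitted model cannot be inverted."""


class NoSteadyStateError(BuccalKineticsError):
    """Raised when no candidate fit window has a positive flux slope."""
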