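"""Exception hierarchy for robustpalmrt."""


class RobustPalmrtError(Exception):
    """Base class for all package-specific errors."""


class DegenerateScaleError(RobustPalmrtError):
    """Raised when a residual scale estimate is exactly zero.

    A zero MAD means more than half of the residuals coincide, which in
    practice indicates that the response is (nearly) contained in the span
    of the controls.  Substituting a scale floor would silently change the
    test statistic, so the condition is surfaced instead.
    """

    def __init__(self, message, residuals=None):
        super().__init__(message)
        self.residuals = residuals


class DegenerateDispersionError(RobustPalmrtError):
    """Raised when a group-mean fitted inter-quantile spread is not positive."""


class FitterError(RobustPalmrtError):
    """Raised when a model-fitting algorithm fails on a concrete design."""


class CalibrationError(RobustPalmrtError):
    """Raised when effect-size calibration cannot bracket the target power."""
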