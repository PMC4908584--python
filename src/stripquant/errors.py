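"""Exception hierarchy for stripquant."""


class StripQuantError(Exception):
    """Base class for all stripquant errors."""


class ConfigurationError(StripQuantError):
    """A generator or analysis configuration violates its invariants."""


class InputError(StripQuantError):
    """An input image, profile, or table is malformed for the requested operation."""


class InvalidTestError(StripQuantError):
    """The strip cannot be read as a valid assay result.

    Raised when fewer than two lines are detected (in a real assay this
    corresponds to a missing control line) or when the control signal is
    zero.  Carries the pipeline stage at which the condition was found.
    """

    def __init__(self, message: str, stage: str = ""):
        super().__init__(message)
        self.stage = stage


class CalibrationError(StripQuantError):
    """Calibration fitting failed or a stored calibration is invalid."""
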