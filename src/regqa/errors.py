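"""Exception hierarchy for regqa."""


class RegQAError(Exception):
    """Base class for all regqa errors."""


class ValidationError(RegQAError):
    """Input violates a documented contract (bad value, incomplete table...)."""


class InputShapeError(ValidationError):
    """A value of the wrong kind was supplied (e.g. mm for an indicator)."""


class EmptyMaskError(RegQAError):
    """A mask that must select at least one voxel is empty."""


class DegenerateInputError(RegQAError):
    """A statistic is undefined for this input (e.g. zero variance)."""


class CalibrationError(RegQAError):
    """Decision-model calibration failed (overlapping intervals, etc.)."""
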