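"""Exception types shared across recruitkit modules."""


class RecruitKitError(Exception):
    """Base class for recruitkit errors."""


class DegenerateInputError(RecruitKitError, ValueError):
    """Raised when an input has no usable contrast or variance.

    Examples: Otsu thresholding of a constant image, %D normalization with
    a maximally-labeled control mass that does not exceed the unexchanged
    control mass.
    """


class TracingError(RecruitKitError, RuntimeError):
    """Raised when a filament centerline cannot be traced between endpoints."""
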