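"""Exception types raised by the pipeline stages."""


class PalmFuseError(ValueError):
    """Base class for all pipeline errors."""


class NoBimodalStructureError(PalmFuseError):
    """Histogram has no valley between two dominant peaks."""


class HandNotOutstretchedError(PalmFuseError):
    """Distance profile does not show 5 fingertips / 4 finger webs."""


class RoiOutOfFrameError(PalmFuseError):
    """The ROI quad falls (partly) outside the image."""


class NoSeparationError(PalmFuseError):
    """Iterative thresholding cannot separate object from background."""
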