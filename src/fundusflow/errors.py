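"""Exception hierarchy for the fundusflow pipeline.

Every stage raises a subclass of :class:`FundusFlowError` so callers (and the
CLI) can attach stage-labelled diagnostics without string matching.
"""


class FundusFlowError(Exception):
    """Base class for all pipeline errors."""


class DegenerateLandmarksError(FundusFlowError):
    """Fovea and disc centers coincide, or the fovea-disc distance is not positive."""


class ImplausibleLandmarksError(FundusFlowError):
    """Fovea-disc axis is anatomically implausible (e.g. near vertical)."""


class LateralityError(FundusFlowError):
    """Unknown laterality code, or a second horizontal flip was requested."""


class InsufficientFeaturesError(FundusFlowError):
    """Too few feature matches survived filtering to estimate a global transform."""


class RegistrationFailureError(FundusFlowError):
    """Robust global transform estimation failed (low inlier fraction, wild scale,
    or degenerate point geometry)."""


class NoSignalError(FundusFlowError):
    """A vessel probability map carries no usable signal (max value too low)."""


class ShapeMismatchError(FundusFlowError):
    """Two rasters that must share a pixel grid do not."""


class FrameMismatchError(FundusFlowError):
    """Objects referenced to different image frames were combined."""
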