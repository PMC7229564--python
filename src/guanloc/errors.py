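"""Exception hierarchy for the GUAN localization pipeline.

Every stage of the pipeline raises a subclass of :class:`GuanlocError`, so the
orchestrator can wrap failures with the stage name while callers can still
catch specific conditions (no salient found, artery not found, ...).
"""

from __future__ import annotations


class GuanlocError(Exception):
    """Base class for all pipeline errors."""


class InputFormatError(GuanlocError):
    """Unreadable or unsupported input file / image format."""


class ValidationError(GuanlocError):
    """Invalid in-memory data (shape mismatch, non-finite values, ...)."""


class ParameterError(GuanlocError):
    """A configuration parameter is outside its valid range."""


class NoEdgeError(GuanlocError):
    """The edge map is empty; no contour can be extracted."""


class ConnectionFailureError(GuanlocError):
    """Breakpoint connection could not reach an image border.

    Attributes
    ----------
    endpoint : tuple of int
        The (column, row) endpoint from which no candidate fragment was
        found within the search range.
    """

    def __init__(self, message: str, endpoint: tuple[int, int] | None = None):
        super().__init__(message)
        self.endpoint = endpoint


class PruningError(GuanlocError):
    """Branch cutting disconnected the border-to-border contour."""


class OutlineError(GuanlocError):
    """The traced contour cannot be reduced to a single-valued outline."""


class FilterLengthError(GuanlocError):
    """The outline is too short for the configured low-pass filter."""


class NoSalientError(GuanlocError):
    """No positively curved point on the smoothed outline (no styloid bump)."""


class NoGuanXError(GuanlocError):
    """No qualifying curvature maximum in the finger-width window.

    Carries the curvature and slope values inside the window for debugging.
    """

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


class ThresholdError(GuanlocError):
    """Region statistics are degenerate; no thresholds can be derived."""


class ArteryNotFoundError(GuanlocError):
    """Too few artery pixels selected to fit a centerline."""


class FitError(GuanlocError):
    """Least-squares artery line fit is singular."""


class LocalizationError(GuanlocError):
    """A located coordinate falls outside the image."""


class GeometryError(GuanlocError):
    """Degenerate camera geometry (vanishing denominator)."""


class OutOfFrameError(GeometryError):
    """A pixel offset lies outside the camera frame."""


class PhantomSpecError(GuanlocError):
    """Inconsistent phantom generation parameters."""


class StageError(GuanlocError):
    """Wraps an error raised inside a named pipeline stage."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause
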