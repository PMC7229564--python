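"""Locating the GUAN x-coordinate on the wrist outline.

The single-valued outline carries pixel staircase steps; it is smoothed with
a minimum-order Butterworth low-pass filter (designed from a pseudo sampling
rate of 70 Hz per pixel column: passband 2 Hz, stopband 3 Hz, 3 dB ripple,
30 dB attenuation) applied zero-phase so landmark columns are not shifted.
The signed curvature of the smoothed outline is computed; the global
positive-curvature maximum is the styloid salient, and the GUAN column is
the first (nearest-to-salient) strict curvature maximum with rising outline
slope within a finger-width window (default 100 px) on the elbow side of
the salient.

Orientation is normalized so that contour protrusions always have positive
curvature and "rising toward the salient" has a fixed sign, regardless of
whether the radial side is the upper or lower image edge and of which hand
is imaged.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .contour import OutlineProfile
from .errors import (
    FilterLengthError,
    NoGuanXError,
    NoSalientError,
    ParameterError,
    ValidationError,
)

__all__ = [
    "FilterSpec",
    "CurvatureProfile",
    "smooth_outline",
    "curvature",
    "curvature_profile",
    "find_salient",
    "locate_x",
]


@dataclass(frozen=True)
class FilterSpec:
    """Butterworth low-pass design targets.

    The outline is treated as a signal sampled at ``sample_rate`` pseudo-Hz
    (one pixel column = one sample), so the 2 Hz passband corner corresponds
    to 2/70 cycles per pixel.
    """

    sample_rate: float = 70.0
    passband_hz: float = 2.0
    stopband_hz: float = 3.0
    passband_ripple_db: float = 3.0
    stopband_atten_db: float = 30.0

    def __post_init__(self) -> None:
        if not 0 < self.passband_hz < self.stopband_hz < self.sample_rate / 2:
            raise ParameterError(
                "need 0 < passband < stopband < sample_rate/2, got "
                f"{self.passband_hz}/{self.stopband_hz}/{self.sample_rate}"
            )

    def design(self) -> tuple[np.ndarray, int]:
        """Minimum-order Butterworth meeting the spec, as (sos, order)."""
        nyq = self.sample_rate / 2.0
        order, wn = signal.buttord(
            self.passband_hz / nyq,
            self.stopband_hz / nyq,
            self.passband_ripple_db,
            self.stopband_atten_db,
        )
        sos = signal.butter(order, wn, btype="low", output="sos")
        return sos, order


def smooth_outline(outline, spec: FilterSpec | None = None) -> np.ndarray:
    """Zero-phase Butterworth smoothing of outline row values.

    Accepts an :class:`OutlineProfile` or a plain value array; returns the
    smoothed values with the same length. Raises
    :class:`FilterLengthError` when the outline is shorter than three times
    the filter order.
    """
    spec = spec or FilterSpec()
    values = outline.rows if isinstance(outline, OutlineProfile) else outline
    values = np.asarray(values, dtype=np.float64)
    sos, order = spec.design()
    if values.size < 3 * order:
        raise FilterLengthError(
            f"outline length {values.size} < 3 x filter order {order}"
        )
    padlen = min(values.size - 1, 6 * order)
    # averaging with the reversed-input pass makes the smoother exactly
    # symmetric under outline reversal (a single forward-backward pass
    # leaves order-dependent boundary transients)
    fwd = signal.sosfiltfilt(sos, values, padlen=padlen)
    bwd = signal.sosfiltfilt(sos, values[::-1], padlen=padlen)[::-1]
    return 0.5 * (fwd + bwd)


def curvature(values, columns=None) -> np.ndarray:
    """Signed curvature of the plane curve (x, v(x)) by finite differences.

    kappa = v'' / (1 + v'^2)^(3/2), central differences with one-sided
    endpoints (via ``np.gradient``). ``columns`` gives the sample positions
    when they are not unit-spaced.
    """
    values = np.asarray(values, dtype=np.float64)
    if values.size < 5:
        raise ValidationError(f"need >= 5 points for curvature, got {values.size}")
    x = np.asarray(columns, dtype=np.float64) if columns is not None else None
    d1 = np.gradient(values, x) if x is not None else np.gradient(values)
    d2 = np.gradient(d1, x) if x is not None else np.gradient(d1)
    return d2 / np.power(1.0 + d1 * d1, 1.5)


@dataclass
class CurvatureProfile:
    """Smoothed outline with its curvature curve, in a normalized frame.

    Arrays are stored in the canonical scan orientation (hand toward
    increasing index): ``columns`` maps each sample back to its image
    column, ``sw`` is the smoothed outline (rows), ``cc`` the curvature with
    protrusions positive, and ``slope`` the outline slope with "rising
    toward the hand-side salient" positive.
    """

    columns: np.ndarray
    sw: np.ndarray
    cc: np.ndarray
    slope: np.ndarray
    side: str = "upper"
    hand_side: str = "right"
    salient_x: int | None = None

    def __post_init__(self) -> None:
        n = len(self.columns)
        if not (len(self.sw) == len(self.cc) == len(self.slope) == n):
            raise ValidationError("profile arrays must share one length")
        if not np.all(np.isfinite(self.cc)):
            raise ValidationError("curvature contains non-finite values")

    def _index_of(self, column: int) -> int:
        hits = np.nonzero(self.columns == column)[0]
        if hits.size == 0:
            raise ValidationError(f"column {column} not in profile")
        return int(hits[0])


def curvature_profile(
    outline: OutlineProfile,
    spec: FilterSpec | None = None,
    side: str = "upper",
    hand_side: str = "right",
) -> CurvatureProfile:
    """Smooth an outline and compute its normalized curvature curve."""
    if side not in ("upper", "lower"):
        raise ParameterError(f"side must be upper/lower, got {side!r}")
    if hand_side not in ("left", "right"):
        raise ParameterError(f"hand_side must be left/right, got {hand_side!r}")
    sw = smooth_outline(outline, spec)
    columns = outline.columns.copy()
    if hand_side == "left":  # mirror so the hand is toward increasing index
        sw = sw[::-1].copy()
        columns = columns[::-1].copy()
    # Protrusions of the upper outline point toward smaller rows (local
    # minima of sw), giving positive second derivative; for the lower
    # outline the sign flips.
    orient = 1.0 if side == "upper" else -1.0
    cc = orient * curvature(sw)
    # Outline "height" rises where rows decrease (upper side); positive
    # slope means climbing toward a protrusion when scanning toward the hand.
    slope = -orient * np.gradient(sw)
    return CurvatureProfile(
        columns=columns, sw=sw, cc=cc, slope=slope, side=side, hand_side=hand_side
    )


def find_salient(profile: CurvatureProfile) -> int:
    """Image column of the styloid salient: global positive-curvature max.

    Ties resolve to the smallest image column.
    """
    cc = profile.cc
    if cc.max() <= 1e-12:  # tolerate filter round-off on flat outlines
        raise NoSalientError("no positively curved point on the outline")
    best = cc.max()
    idxs = np.nonzero(cc == best)[0]
    cols = profile.columns[idxs]
    idx = idxs[int(np.argmin(cols))]
    profile.salient_x = int(profile.columns[idx])
    return profile.salient_x


def locate_x(
    profile: CurvatureProfile,
    window_px: int = 100,
    scan: str = "nearest",
    slope_min: float = 0.02,
) -> int:
    """GUAN x-coordinate: recess-side curvature maximum near the salient.

    Scans the open window of ``window_px`` columns on the elbow side of the
    salient for a strict local maximum of the curvature whose outline slope
    is positive (rising toward the salient). ``slope_min`` is the numerical
    floor for "positive": residual pixel-staircase ripple after smoothing
    produces spurious curvature maxima on flat contour stretches whose
    slopes are two orders of magnitude below any real recess shoulder.
    ``scan='nearest'`` returns the qualifying column closest to the
    salient; ``scan='farthest'`` the one closest to the window edge. A
    candidate exactly ``window_px`` away is excluded (half-open window).
    """
    if scan not in ("nearest", "farthest"):
        raise ParameterError(f"scan must be nearest/farthest, got {scan!r}")
    if profile.salient_x is None:
        find_salient(profile)
    s = profile._index_of(profile.salient_x)
    cc, slope = profile.cc, profile.slope
    lo = max(1, s - window_px + 1)  # window is open at distance window_px
    candidates = []
    for j in range(s - 1, lo - 1, -1):
        if j + 1 >= cc.size:
            continue
        if cc[j] > cc[j - 1] and cc[j] > cc[j + 1] and slope[j] > slope_min:
            candidates.append(j)
    if not candidates:
        raise NoGuanXError(
            "no curvature maximum with rising slope in the finger-width window",
            diagnostics={
                "salient_x": profile.salient_x,
                "window_cc": cc[max(0, s - window_px) : s + 1].tolist(),
                "window_slope": slope[max(0, s - window_px) : s + 1].tolist(),
            },
        )
    j = candidates[0] if scan == "nearest" else candidates[-1]
    return int(profile.columns[j])
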