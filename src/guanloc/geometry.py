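"""Pixel-to-millimetre mapping on the tilted wrist bracket.

The thermal camera looks straight down from height ``h`` above the
reference point O on the horizontal plane; the bracket plane through O is
tilted by ``alpha``. A pixel offset X from the frame centre along the tilt
axis subtends the step angle

    dtheta = X / (extent/2) * theta,

where ``theta`` is the half field angle along that axis. The intersection
of the viewing ray with the tilted plane follows from the sine theorem and
splits into two cases: on the raised (near) side of O the horizontal
coordinate is ``+HP`` with denominator sin(90 - dtheta + alpha); on the
lowered (far) side it is ``-HP`` with denominator sin(90 - dtheta - alpha).
``AP`` is the slant range from the camera to the intersection row; the
cross coordinate is ``y = AP * tan(dbeta) * sign(Y)`` with ``dbeta``
proportional to the cross-axis pixel offset.

Sign convention: X > 0 toward the raised/near end of the bracket, so the
along-bracket coordinate x_P is strictly increasing in X and reduces to
``h * tan(dtheta)`` at zero tilt.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .errors import GeometryError, OutOfFrameError, ParameterError
from .io import GuanResult

__all__ = [
    "CameraGeometry",
    "WorldPoint",
    "step_angle_vertical",
    "pixel_to_world_x",
    "pixel_to_world_y",
    "pixel_to_world",
    "map_guan",
]

_EPS = 1e-9


@dataclass(frozen=True)
class CameraGeometry:
    """Camera/bracket parameters.

    theta_deg, beta_deg : half field angles (degrees) along the vertical
        (tilt) and horizontal (cross) pixel axes of the camera frame.
    h_mm : perpendicular camera-to-plane distance (mm), foot at O.
    alpha_deg : bracket tilt (degrees); must satisfy alpha < 90 - theta so
        the far-side denominator stays positive.
    height_px, width_px : frame extents along the vertical/horizontal axes.
    """

    theta_deg: float
    beta_deg: float
    h_mm: float
    alpha_deg: float
    height_px: int
    width_px: int

    def __post_init__(self) -> None:
        if not 0 < self.theta_deg < 90 or not 0 < self.beta_deg < 90:
            raise ParameterError("half field angles must be in (0, 90) degrees")
        if not 0 <= self.alpha_deg < 90 - self.theta_deg:
            raise ParameterError(
                f"tilt alpha={self.alpha_deg} must be in [0, 90 - theta)"
            )
        if self.h_mm <= 0:
            raise ParameterError("camera distance h_mm must be positive")
        if self.height_px < 2 or self.width_px < 2:
            raise ParameterError("frame extents must be >= 2 px")


@dataclass(frozen=True)
class WorldPoint:
    x_mm: float
    y_mm: float


def step_angle_vertical(X: float, geom: CameraGeometry) -> float:
    """Step angle (degrees) of a signed pixel offset along the tilt axis."""
    half = geom.height_px / 2.0
    if abs(X) > half + _EPS:
        raise OutOfFrameError(f"|X|={abs(X)} exceeds half frame {half}")
    return X / half * geom.theta_deg


def pixel_to_world_x(X: float, geom: CameraGeometry) -> tuple[float, float]:
    """Map a tilt-axis pixel offset to (x_P mm, AP mm).

    X > 0 selects the raised-side case (x_P = +HP), X < 0 the lowered-side
    case (x_P = -HP); AP is the slant range used for the cross coordinate.
    """
    dtheta = math.radians(abs(step_angle_vertical(X, geom)))
    alpha = math.radians(geom.alpha_deg)
    h = geom.h_mm
    if X >= 0:  # raised / near side: sin(90 - dtheta + alpha)
        denom = math.cos(dtheta - alpha)
    else:  # lowered / far side: sin(90 - dtheta - alpha)
        denom = math.cos(dtheta + alpha)
    if denom <= _EPS:
        raise GeometryError("viewing ray nearly parallel to the bracket plane")
    hp = math.sin(dtheta) * h / denom * math.cos(alpha)
    ap = math.cos(alpha) * h / denom
    return (hp if X >= 0 else -hp), ap


def pixel_to_world_y(Y: float, ap: float, geom: CameraGeometry) -> float:
    """Map a cross-axis pixel offset to y_P mm at slant range ``ap``."""
    half = geom.width_px / 2.0
    if abs(Y) > half + _EPS:
        raise OutOfFrameError(f"|Y|={abs(Y)} exceeds half frame {half}")
    if ap <= 0:
        raise GeometryError("slant range AP must be positive")
    dbeta = math.radians(abs(Y) / half * geom.beta_deg)
    if dbeta >= math.pi / 2:
        raise OutOfFrameError("cross step angle reaches 90 degrees")
    return ap * math.tan(dbeta) * float(np.sign(Y))


def pixel_to_world(
    col: float, row: float, geom: CameraGeometry, tilt_axis: str = "cols"
) -> WorldPoint:
    """World coordinates of a pixel.

    ``tilt_axis`` names the image axis along which the bracket is tilted
    (the arm/elbow direction). With ``tilt_axis='cols'`` (landscape wrist
    images, arm along columns) the column offset feeds the tilt mapping and
    the row offset the cross mapping; ``'rows'`` swaps them. The raised end
    is at pixel coordinate 0 of the tilt axis, so the frame centre maps to
    (0, 0) mm.
    """
    if tilt_axis == "cols":
        geom_t = replace(geom, height_px=geom.width_px, width_px=geom.height_px)
        X = geom.width_px / 2.0 - col
        Y = row - geom.height_px / 2.0
    elif tilt_axis == "rows":
        geom_t = geom
        X = geom.height_px / 2.0 - row
        Y = col - geom.width_px / 2.0
    else:
        raise ParameterError(f"tilt_axis must be cols/rows, got {tilt_axis!r}")
    x_mm, ap = pixel_to_world_x(X, geom_t)
    y_mm = pixel_to_world_y(Y, ap, geom_t)
    return WorldPoint(x_mm=x_mm, y_mm=y_mm)


def map_guan(
    result: GuanResult, geom: CameraGeometry, tilt_axis: str = "cols"
) -> GuanResult:
    """Attach world coordinates (and crease distance) to a pixel result.

    The crease reference shares the GUAN's cross coordinate, so the
    crease-to-GUAN distance is the along-bracket (tilt-axis) separation of
    the two columns evaluated at the GUAN row.
    """
    guan = pixel_to_world(result.x0_px, result.y0_px, geom, tilt_axis)
    out = GuanResult(
        x0_px=result.x0_px,
        y0_px=result.y0_px,
        x_world_mm=guan.x_mm,
        y_world_mm=guan.y_mm,
        crease_x_px=result.crease_x_px,
        diagnostics=dict(result.diagnostics),
    )
    if result.crease_x_px is not None:
        crease = pixel_to_world(
            result.crease_x_px, result.y0_px, geom, tilt_axis
        )
        if tilt_axis == "cols":  # columns feed the along-bracket mapping
            out.x_distance_mm = abs(crease.x_mm - guan.x_mm)
        else:  # columns feed the cross mapping
            out.x_distance_mm = abs(crease.y_mm - guan.y_mm)
    return out
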