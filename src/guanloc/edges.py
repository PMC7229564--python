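"""Arbitrary-angle edge detection.

The detector works in three steps:

1. a first-derivative-of-Gaussian gradient-magnitude response at scale
   ``sigma`` (reflective boundaries);
2. for each detection angle in [0°, 45°], the image grid is partitioned into
   digital pixel lines at that angle and the response is non-maximum
   suppressed *along each line* (a pixel survives only if it is a strict
   local maximum along its line and exceeds the threshold);
3. the per-angle edge maps are superimposed (logical OR), and the 0°–45°
   range is extended to the full circle by applying the same machinery
   under grid symmetries (rotations, flips, transposition) chosen so that
   every undirected line direction is scanned exactly once.

Two digital-line constructions are provided: ``compact`` (Bresenham-style,
rounding the ideal line) and ``sparse`` (floor-based, diagonal-skipping).
For every angle either construction partitions the grid exactly: each pixel
belongs to exactly one line.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .errors import NoEdgeError, ParameterError, ValidationError
from .io import ThermalImage

__all__ = [
    "EdgeMap",
    "PixelLine",
    "gaussian_gradient",
    "decompose_pixel_lines",
    "nms_along_lines",
    "detect_edges",
]


@dataclass
class EdgeMap:
    """Binary edge image with the detection angles that produced it."""

    mask: np.ndarray
    angles_used: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2:
            raise ValidationError("edge mask must be 2-D")

    @property
    def shape(self) -> tuple[int, int]:
        return self.mask.shape

    def count(self) -> int:
        return int(self.mask.sum())


@dataclass
class PixelLine:
    """Ordered pixels of one digital line at a given angle.

    ``coords`` is an (N, 2) array of (column, row) pairs ordered by column;
    consecutive pixels are 8-connected.
    """

    coords: np.ndarray
    angle_deg: float

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=int).reshape(-1, 2)


def _as_array(image) -> np.ndarray:
    if isinstance(image, ThermalImage):
        return image.pixels
    return np.asarray(image, dtype=np.float64)


def gaussian_gradient(image, sigma: float) -> np.ndarray:
    """Gradient-magnitude response from derivative-of-Gaussian filtering.

    Reflective boundary handling; same shape as the input.
    """
    if sigma <= 0:
        raise ParameterError(f"sigma must be positive, got {sigma}")
    arr = _as_array(image)
    gx = ndimage.gaussian_filter(arr, sigma, order=(0, 1), mode="reflect")
    gy = ndimage.gaussian_filter(arr, sigma, order=(1, 0), mode="reflect")
    return np.hypot(gx, gy)


def _row_offsets(width: int, angle_deg: float, connection: str) -> np.ndarray:
    """Per-column row offset of the ideal line through row 0 at ``angle_deg``."""
    slope = math.tan(math.radians(angle_deg))
    ideal = slope * np.arange(width)
    if connection == "compact":
        return np.floor(ideal + 0.5).astype(int)
    if connection == "sparse":
        return np.floor(ideal).astype(int)
    raise ParameterError(f"unknown connection {connection!r}")


def decompose_pixel_lines(
    shape: tuple[int, int], angle_deg: float, connection: str = "compact"
) -> list[PixelLine]:
    """Partition an (height, width) grid into digital lines at one angle.

    Every pixel belongs to exactly one line. A pixel (column c, row r) lies
    on the line with key ``r + offset(c)`` where ``offset`` tracks the ideal
    line of the requested angle; rounding (``compact``) vs flooring
    (``sparse``) selects the digital-line construction.
    """
    if not 0 <= angle_deg <= 45:
        raise ParameterError(
            f"angle must be in [0, 45] degrees, got {angle_deg}; other "
            "directions are realized by the symmetry extension"
        )
    h, w = shape
    off = _row_offsets(w, angle_deg, connection)
    lines = []
    for key in range(0, h + off[-1]):
        cols = np.nonzero((key - off >= 0) & (key - off < h))[0]
        if cols.size == 0:
            continue
        rows = key - off[cols]
        lines.append(
            PixelLine(np.column_stack([cols, rows]), angle_deg=angle_deg)
        )
    return lines


def nms_along_lines(response, lines, threshold: float) -> EdgeMap:
    """Mark local maxima of the response along each pixel line.

    A pixel is marked iff its response strictly exceeds the next line
    neighbour, is at least equal to the previous one, and reaches
    ``threshold``. The asymmetric plateau rule marks exactly one pixel of an
    exactly tied pair, which arises whenever an intensity step falls between
    two pixel rows. Line endpoints are never marked (a local maximum needs
    two neighbours).
    """
    resp = np.asarray(response, dtype=np.float64)
    mask = np.zeros(resp.shape, dtype=bool)
    for line in lines:
        coords = line.coords
        if coords.shape[0] < 3:
            continue
        cols, rows = coords[:, 0], coords[:, 1]
        if np.any(rows >= resp.shape[0]) or np.any(cols >= resp.shape[1]):
            raise ValidationError("pixel line exceeds response shape")
        vals = resp[rows, cols]
        interior = (
            (vals[1:-1] >= vals[:-2])
            & (vals[1:-1] > vals[2:])
            & (vals[1:-1] >= threshold)
        )
        mask[rows[1:-1][interior], cols[1:-1][interior]] = True
    angles = sorted({float(line.angle_deg) for line in lines})
    return EdgeMap(mask, angles_used=angles)


def _nms_one_angle(
    resp: np.ndarray, angle_deg: float, connection: str, threshold: float
) -> np.ndarray:
    """Vectorized per-line NMS for one angle on the full grid.

    Equivalent to ``nms_along_lines(resp, decompose_pixel_lines(...))``:
    the line neighbour of (r, c) at column c+1 sits at row r - d(c) where
    d(c) = offset(c+1) - offset(c) in {0, 1}.
    """
    h, w = resp.shape
    off = _row_offsets(w, angle_deg, connection)
    step = np.diff(off)  # length w-1, values in {0, 1}

    nxt = np.full((h, w), np.inf)
    prv = np.full((h, w), np.inf)
    rows = np.arange(h)[:, None]
    # neighbour toward column c+1 (for columns 0..w-2)
    r_next = rows - step[None, :]
    valid = r_next >= 0
    cols_idx = np.broadcast_to(np.arange(w - 1)[None, :], (h, w - 1))
    nxt[:, :-1][valid] = resp[r_next[valid], cols_idx[valid] + 1]
    # neighbour toward column c-1 (for columns 1..w-1)
    r_prev = rows + step[None, :]
    valid = r_prev < h
    prev_cols = np.broadcast_to(np.arange(1, w)[None, :], (h, w - 1))
    prv[:, 1:][valid] = resp[r_prev[valid], prev_cols[valid] - 1]

    return (resp > nxt) & (resp >= prv) & (resp >= threshold)


# Grid symmetries realizing the angle extension: [0, 45] degrees under these
# four ops covers every undirected line direction in [0, 180) exactly once
# (hence all of 0-360 for undirected edges). The remaining four dihedral
# elements only reverse the scan order along already-covered lines, which
# would mark both pixels of an exactly tied response pair.
_SYMMETRIES = [
    (lambda a: a, lambda a: a),  # [0, 45]
    (lambda a: a.T, lambda a: a.T),  # [45, 90]
    (lambda a: np.rot90(a, 1), lambda a: np.rot90(a, -1)),  # [90, 135]
    (np.fliplr, np.fliplr),  # [135, 180]
]


def detect_edges(
    image,
    sigma: float = 2.0,
    n_angles: int = 8,
    threshold_quantile: float = 0.70,
    connection: str = "compact",
    noise_floor_mult: float = 8.0,
) -> EdgeMap:
    """Multi-angle edge detection over the full 0°–360° range.

    ``n_angles`` equally spaced angles in [0°, 45°] are swept; each per-angle
    NMS is applied under the four grid symmetries that extend the angles to
    every undirected direction, and the results are OR-ed.
    The response threshold is the ``threshold_quantile`` quantile of the
    positive response values, floored at ``noise_floor_mult`` times the
    median of the full response map. On a clean image most responses are
    exactly zero and the floor is inert; with broadband sensor noise every
    response is positive, the quantile collapses to the noise level, and
    the floor (several times the typical noise response) takes over. A
    constant image yields an empty edge map, not an error.
    """
    if n_angles < 2:
        raise ParameterError("n_angles must be >= 2")
    if not 0 < threshold_quantile < 1:
        raise ParameterError("threshold_quantile must be in (0, 1)")
    arr = _as_array(image)
    resp = gaussian_gradient(arr, sigma)
    positive = resp[resp > 0]
    angles = list(np.linspace(0.0, 45.0, n_angles))
    if positive.size == 0:
        return EdgeMap(np.zeros(resp.shape, dtype=bool), angles_used=angles)
    threshold = float(
        max(
            np.quantile(positive, threshold_quantile),
            noise_floor_mult * np.median(resp),
        )
    )
    mask = np.zeros(resp.shape, dtype=bool)
    for fwd, inv in _SYMMETRIES:
        sub = np.ascontiguousarray(fwd(arr))
        # directional gate: a scan marks a pixel only when the local
        # gradient lies within 45 degrees of the scan line, so suppression
        # acts along the gradient (scans running along an edge would
        # otherwise mark every noise ripple in the high-response band).
        gc = ndimage.gaussian_filter(sub, sigma, order=(0, 1), mode="reflect")
        gr = ndimage.gaussian_filter(sub, sigma, order=(1, 0), mode="reflect")
        resp_sub = np.hypot(gc, gr)
        for angle in angles:
            phi = math.radians(angle)
            # line tangent in (col,row) is (cos, -sin): rows shrink rightward
            along = np.abs(gc * math.cos(phi) - gr * math.sin(phi))
            across = np.abs(gc * math.sin(phi) + gr * math.cos(phi))
            marks = _nms_one_angle(resp_sub, angle, connection, threshold)
            marks &= along >= across
            mask |= inv(marks)
    return EdgeMap(mask, angles_used=angles)


def require_nonempty(edges: EdgeMap) -> EdgeMap:
    if not edges.mask.any():
        raise NoEdgeError("edge map is empty")
    return edges
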