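"""Wrist contour extraction from an edge map.

Pipeline: keep the largest 8-connected edge component; if it does not reach
both lateral image borders, iteratively bridge breakpoints to neighbouring
edge fragments (searching a 2-pixel range in five leftward/vertical
directions from the left endpoint, mirrored on the right); prune short side
branches at junctions; finally collapse the traced pixel set to a
single-valued outline row-per-column profile.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.draw import line as draw_line

from .edges import EdgeMap
from .errors import (
    ConnectionFailureError,
    NoEdgeError,
    OutlineError,
    PruningError,
    ValidationError,
)

__all__ = [
    "PixelPath",
    "OutlineProfile",
    "max_connected_domain",
    "connect_breakpoints",
    "cut_branches",
    "to_outline",
]

_EIGHT = np.ones((3, 3), dtype=int)

# Search directions (dcol, drow) used when extending the contour toward the
# left border: up, left-up, left, left-down, down. The right-side search
# mirrors the horizontal component.
_LEFT_DIRECTIONS = [(0, -1), (-1, -1), (-1, 0), (-1, 1), (0, 1)]
_RIGHT_DIRECTIONS = [(0, -1), (1, -1), (1, 0), (1, 1), (0, 1)]


@dataclass
class PixelPath:
    """A set of edge pixels forming (part of) the wrist contour.

    ``coords`` is an (N, 2) int array of (column, row) pairs, sorted by
    column then row. ``shape`` records the source image shape so border
    checks and rasterization do not need extra context.
    """

    coords: np.ndarray
    shape: tuple[int, int]
    closed: bool = False

    def __post_init__(self) -> None:
        coords = np.asarray(self.coords, dtype=int).reshape(-1, 2)
        order = np.lexsort((coords[:, 1], coords[:, 0]))
        self.coords = coords[order]
        if np.unique(self.coords, axis=0).shape[0] != self.coords.shape[0]:
            raise ValidationError("pixel path contains repeated coordinates")

    def __len__(self) -> int:
        return self.coords.shape[0]

    def to_mask(self) -> np.ndarray:
        mask = np.zeros(self.shape, dtype=bool)
        mask[self.coords[:, 1], self.coords[:, 0]] = True
        return mask

    @classmethod
    def from_mask(cls, mask: np.ndarray, closed: bool = False) -> "PixelPath":
        rows, cols = np.nonzero(mask)
        return cls(np.column_stack([cols, rows]), shape=mask.shape, closed=closed)

    def spans_lateral_borders(self) -> bool:
        cols = self.coords[:, 0]
        return cols.min() == 0 and cols.max() == self.shape[1] - 1


@dataclass
class OutlineProfile:
    """Single-valued wrist outline: one row value per contiguous column."""

    columns: np.ndarray
    rows: np.ndarray

    def __post_init__(self) -> None:
        self.columns = np.asarray(self.columns, dtype=int)
        self.rows = np.asarray(self.rows, dtype=np.float64)
        if self.columns.size != self.rows.size:
            raise ValidationError("columns and rows must have equal length")
        if self.columns.size and not np.all(np.diff(self.columns) == 1):
            raise ValidationError("columns must be contiguous and increasing")

    @property
    def col_start(self) -> int:
        return int(self.columns[0])

    @property
    def col_end(self) -> int:
        return int(self.columns[-1])

    def __len__(self) -> int:
        return self.columns.size


def _largest_component(mask: np.ndarray) -> np.ndarray:
    """Boolean mask of the largest 8-connected component.

    Ties broken by widest bounding box, then by topmost pixel.
    """
    labels, n = ndimage.label(mask, structure=_EIGHT)
    if n == 0:
        raise NoEdgeError("edge map is empty")
    sizes = np.bincount(labels.ravel())[1:]
    best = np.nonzero(sizes == sizes.max())[0] + 1
    if best.size > 1:
        slices = ndimage.find_objects(labels)
        widths = [slices[i - 1][1].stop - slices[i - 1][1].start for i in best]
        widest = max(widths)
        best = [
            lab for lab, wdt in zip(best, widths) if wdt == widest
        ]
        if len(best) > 1:
            tops = [slices[i - 1][0].start for i in best]
            best = [best[int(np.argmin(tops))]]
    return labels == best[0]


def max_connected_domain(edges: EdgeMap) -> PixelPath:
    """Largest 8-connected component of the edge map as a pixel path."""
    return PixelPath.from_mask(_largest_component(edges.mask))


def _endpoint(coords: np.ndarray, side: str) -> tuple[int, int]:
    cols = coords[:, 0]
    sel = cols == (cols.min() if side == "left" else cols.max())
    rows = coords[sel, 1]
    col = int(cols.min() if side == "left" else cols.max())
    return col, int(rows.min())


def connect_breakpoints(
    edges: EdgeMap, component: PixelPath, search_range: int = 2
) -> PixelPath:
    """Bridge the component to both lateral borders via nearby fragments.

    From the current leftmost pixel, other edge fragments are searched at
    Chebyshev distance 1..``search_range`` along the five leftward/vertical
    directions; the first hit is bridged by straight-line pixel interpolation
    and merged, and the search repeats from the new leftmost pixel until the
    left border is reached. The right side proceeds symmetrically. A
    component that already spans both borders is returned unchanged.
    """
    if component.spans_lateral_borders():
        return component
    mask = edges.mask.copy()
    current = component.to_mask()
    h, w = mask.shape
    n_fragments = int(ndimage.label(mask, structure=_EIGHT)[1])

    for side, directions, border in (
        ("left", _LEFT_DIRECTIONS, 0),
        ("right", _RIGHT_DIRECTIONS, w - 1),
    ):
        for _ in range(n_fragments + 2):
            coords = np.column_stack(np.nonzero(current))[:, ::-1]  # (col,row)
            col, row = _endpoint(coords, side)
            if col == border:
                break
            hit = None
            for dist in range(1, search_range + 1):
                for dc, dr in directions:
                    c2, r2 = col + dc * dist, row + dr * dist
                    if 0 <= c2 < w and 0 <= r2 < h and mask[r2, c2] and not current[r2, c2]:
                        hit = (c2, r2)
                        break
                if hit:
                    break
            if hit is None:
                raise ConnectionFailureError(
                    f"no edge fragment within {search_range} px of {side} "
                    f"endpoint ({col}, {row})",
                    endpoint=(col, row),
                )
            rr, cc = draw_line(row, col, hit[1], hit[0])
            mask[rr, cc] = True
            labels, _ = ndimage.label(mask, structure=_EIGHT)
            current = labels == labels[row, col]
        else:
            raise ConnectionFailureError(
                f"{side} border not reached after merging all fragments",
                endpoint=_endpoint(
                    np.column_stack(np.nonzero(current))[:, ::-1], side
                ),
            )
    return PixelPath.from_mask(current)


def _neighbor_counts(mask: np.ndarray) -> np.ndarray:
    counts = ndimage.convolve(mask.astype(int), _EIGHT, mode="constant") - mask
    return np.where(mask, counts, 0)


def cut_branches(path: PixelPath, max_spur_len: int = 15) -> PixelPath:
    """Prune short side branches (spurs) at contour junctions.

    From every free endpoint the chain is traced until it meets a junction
    pixel (>= 3 neighbours); chains shorter than ``max_spur_len`` are
    deleted. Pruning that would split the contour raises
    :class:`PruningError`.
    """
    mask = path.to_mask()
    n_before = int(ndimage.label(mask, structure=_EIGHT)[1])
    changed = True
    while changed:
        changed = False
        counts = _neighbor_counts(mask)
        if not np.any(counts >= 3):
            break
        endpoints = np.column_stack(np.nonzero(mask & (counts == 1)))

        def free_neighbors(r, c, chain):
            return [
                (r + dr, c + dc)
                for dr in (-1, 0, 1)
                for dc in (-1, 0, 1)
                if (dr or dc)
                and 0 <= r + dr < mask.shape[0]
                and 0 <= c + dc < mask.shape[1]
                and mask[r + dr, c + dc]
                and (r + dr, c + dc) not in chain
            ]

        for r0, c0 in endpoints:
            if not mask[r0, c0]:
                continue
            chain = [(int(r0), int(c0))]
            reached_junction = False
            while len(chain) <= max_spur_len:
                nbrs = free_neighbors(*chain[-1], chain)
                if len(nbrs) == 0:
                    break
                if len(nbrs) >= 2:
                    # current pixel touches the main path in several places:
                    # it is the last spur pixel
                    reached_junction = True
                    break
                chain.append(nbrs[0])
            if reached_junction and len(chain) < max_spur_len:
                for r, c in chain:
                    mask[r, c] = False
                changed = True
        if changed:
            continue
    n_after = int(ndimage.label(mask, structure=_EIGHT)[1])
    if n_after != n_before:
        raise PruningError(
            f"branch cutting split the contour ({n_before} -> {n_after} parts)"
        )
    return PixelPath.from_mask(mask, closed=path.closed)


def to_outline(path: PixelPath, side: str = "upper") -> OutlineProfile:
    """Collapse a contour pixel set to one row per column.

    Columns with multiple contour rows take the minimum row for
    ``side='upper'`` (the radial side on top) and the maximum for
    ``side='lower'``. Column gaps of up to 2 are filled by linear
    interpolation; wider gaps raise :class:`OutlineError`.
    """
    if side not in ("upper", "lower"):
        raise ValidationError(f"side must be 'upper' or 'lower', got {side!r}")
    coords = path.coords
    if coords.shape[0] == 0:
        raise OutlineError("empty pixel path")
    col_start, col_end = int(coords[:, 0].min()), int(coords[:, 0].max())
    n = col_end - col_start + 1
    fill = np.inf if side == "upper" else -np.inf
    per_col = np.full(n, fill)
    idx = coords[:, 0] - col_start
    if side == "upper":
        np.minimum.at(per_col, idx, coords[:, 1])
    else:
        np.maximum.at(per_col, idx, coords[:, 1])
    missing = ~np.isfinite(per_col)
    if missing.any():
        # locate runs of missing columns
        padded = np.concatenate([[False], missing, [False]])
        starts = np.nonzero(padded[1:] & ~padded[:-1])[0]
        ends = np.nonzero(~padded[1:] & padded[:-1])[0]
        for s, e in zip(starts, ends):
            if e - s > 2:
                raise OutlineError(
                    f"outline gap of {e - s} columns at {col_start + s}"
                )
            if s == 0 or e == n:
                raise OutlineError("outline gap touches path extremity")
            left, right = per_col[s - 1], per_col[e]
            for k in range(s, e):
                t = (k - (s - 1)) / (e - (s - 1))
                per_col[k] = left + t * (right - left)
    return OutlineProfile(np.arange(col_start, col_end + 1), per_col)
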