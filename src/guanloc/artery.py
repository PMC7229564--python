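"""Locating the GUAN y-coordinate from the radial-artery heat stripe.

A square region (default 10x10) is placed at every interior edge point and
its intensity mean and population standard deviation are computed. Regions
whose statistics fall inside percentile-window thresholds select candidate
artery pixels: the artery is among the warmest structures (high region
mean) and its boundary contrast is the smallest among true edges (low-to-
moderate region std; the wrist silhouette, with the largest thermal
contrast, occupies the top std percentiles). The union of qualifying
regions forms the partial-artery image; the per-column mean row of its
pixels is fitted with an ordinary least-squares line, and the GUAN row is
the line evaluated at the GUAN column.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .edges import EdgeMap
from .errors import (
    ArteryNotFoundError,
    FitError,
    LocalizationError,
    ParameterError,
    ThresholdError,
    ValidationError,
)
from .io import ThermalImage

__all__ = [
    "RegionStats",
    "Thresholds",
    "ArteryModel",
    "region_stats",
    "derive_thresholds",
    "select_artery_pixels",
    "fit_artery_line",
    "locate_y",
]


@dataclass
class RegionStats:
    """Mean/std of the square region anchored at one edge point.

    A region of even size ``s`` centered at (col, row) spans rows
    [row - s/2, row + s/2 - 1] and the analogous columns.
    """

    center: tuple[int, int]  # (column, row)
    mean: float
    std: float


@dataclass
class Thresholds:
    mean_min: float
    mean_max: float
    std_min: float
    std_max: float


@dataclass
class ArteryModel:
    """Selected artery pixels, their per-column mean rows, and the line fit."""

    pixels: np.ndarray  # (N, 2) (column, row)
    columns: np.ndarray
    col_means: np.ndarray
    slope: float | None = None
    intercept: float | None = None
    diagnostics: dict = field(default_factory=dict)


def _window_sums(arr: np.ndarray, size: int) -> tuple[np.ndarray, np.ndarray]:
    """Sliding-window sums of arr and arr**2 for all top-left anchors."""
    pad = np.zeros((arr.shape[0] + 1, arr.shape[1] + 1))
    np.cumsum(np.cumsum(arr, axis=0), axis=1, out=pad[1:, 1:])
    s = (
        pad[size:, size:]
        - pad[:-size, size:]
        - pad[size:, :-size]
        + pad[:-size, :-size]
    )
    return s


def region_stats(
    image: ThermalImage, edges: EdgeMap, size: int = 10
) -> list[RegionStats]:
    """Region mean and population std at every interior edge point.

    Edge points whose region would leave the image are skipped.
    """
    if size < 4 or size % 2 != 0:
        raise ParameterError(f"region size must be even and >= 4, got {size}")
    arr = image.pixels
    if edges.mask.shape != arr.shape:
        raise ValidationError("edge map shape does not match image")
    half = size // 2
    h, w = arr.shape
    sums = _window_sums(arr, size)
    sqsums = _window_sums(arr * arr, size)
    n = float(size * size)
    rows, cols = np.nonzero(edges.mask)
    interior = (rows >= half) & (rows <= h - half) & (cols >= half) & (cols <= w - half)
    rows, cols = rows[interior], cols[interior]
    r0, c0 = rows - half, cols - half  # top-left anchors
    means = sums[r0, c0] / n
    variances = np.maximum(sqsums[r0, c0] / n - means * means, 0.0)
    stds = np.sqrt(variances)
    return [
        RegionStats(center=(int(c), int(r)), mean=float(m), std=float(s))
        for c, r, m, s in zip(cols, rows, means, stds)
    ]


def derive_thresholds(
    image: ThermalImage,
    stats: list[RegionStats],
    method: str = "otsu",
    mean_pct: tuple[float, float] = (70.0, 99.5),
    std_pct: tuple[float, float] = (0.0, 60.0),
) -> Thresholds:
    """Thresholds from the histograms of the region statistics.

    The region means of a thermal wrist image are bimodal: silhouette
    boundaries average skin and background, artery boundaries sit near skin
    temperature and above. Likewise the region stds: the silhouette has the
    largest thermal contrast, the artery boundary the smallest among true
    edges. The default ``method='otsu'`` places the lower mean bound and
    the upper std bound at the Otsu split of the respective histogram,
    which is invariant to how many edge points each structure contributes;
    ``method='percentile'`` uses the config-exposed percentile windows
    instead. The upper mean bound always trims the hottest 0.5% of regions.
    """
    if len(stats) < 10:
        raise ValidationError(f"need >= 10 region stats, got {len(stats)}")
    means = np.array([s.mean for s in stats])
    stds = np.array([s.std for s in stats])
    if np.ptp(means) == 0 and np.ptp(stds) == 0:
        raise ThresholdError("all regions identical; cannot derive thresholds")
    if method == "otsu":
        from skimage.filters import threshold_otsu

        def split(v):
            # Otsu bin edge, recentred in the empty gap between the classes
            # (the Otsu criterion is flat across a gap and skimage returns
            # an arbitrary edge of the plateau)
            t = float(threshold_otsu(v))
            below, above = v[v <= t], v[v > t]
            if below.size and above.size:
                t = 0.5 * (below.max() + above.min())
            return t

        mean_min = split(means) if np.ptp(means) > 0 else means[0]
        std_max = split(stds) if np.ptp(stds) > 0 else stds[0]
        # no upper mean cut: saturated interiors are not edge points, and
        # the warmest regions are legitimate artery-boundary regions. The
        # lower std bound excludes near-flat regions (stray noise marks on
        # response tails) whose contrast is far below any true boundary.
        return Thresholds(
            mean_min=mean_min,
            mean_max=float(np.inf),
            std_min=std_max / 4.0,
            std_max=std_max,
        )
    if method == "percentile":
        return Thresholds(
            mean_min=float(np.percentile(means, mean_pct[0])),
            mean_max=float(np.percentile(means, mean_pct[1])),
            std_min=float(np.percentile(stds, std_pct[0])),
            std_max=float(np.percentile(stds, std_pct[1])),
        )
    raise ParameterError(f"unknown threshold method {method!r}")


def select_artery_pixels(
    image: ThermalImage,
    stats: list[RegionStats],
    thresholds: Thresholds,
    size: int = 10,
    band: tuple[int, int] | None = None,
    row_min: np.ndarray | None = None,
) -> ArteryModel:
    """Union of pixels of all regions whose stats satisfy the thresholds.

    ``band`` optionally restricts selected pixels to a column interval
    before the per-column mean rows are computed. ``row_min`` (one value
    per image column) excludes regions centred above it: the radial artery
    is interior to the wrist, so the pipeline passes the extracted outline
    plus a margin to keep low-contrast silhouette regions out of the fit.
    """
    half = size // 2
    mask = np.zeros(image.shape, dtype=bool)
    n_regions = 0
    for s in stats:
        c, r = s.center
        if row_min is not None and r < row_min[c]:
            continue
        if (
            thresholds.mean_min <= s.mean <= thresholds.mean_max
            and thresholds.std_min <= s.std <= thresholds.std_max
        ):
            mask[r - half : r + half, c - half : c + half] = True
            n_regions += 1
    if band is not None:
        keep = np.zeros_like(mask)
        keep[:, max(0, band[0]) : band[1] + 1] = True
        mask &= keep
    rows, cols = np.nonzero(mask)
    uniq, counts = np.unique(cols, return_counts=True)
    if uniq.size >= 2:
        # columns at the ends of the selected span are covered by only a
        # sliver of a qualifying region; their mean rows are biased and
        # leverage the line fit, so poorly covered columns are dropped.
        keep = counts >= 0.5 * np.median(counts)
        uniq, counts = uniq[keep], counts[keep]
    if uniq.size < 2:
        raise ArteryNotFoundError(
            f"only {uniq.size} well-covered column(s) selected "
            f"({n_regions} qualifying regions)"
        )
    col_means = np.array([rows[cols == c].mean() for c in uniq], dtype=np.float64)
    return ArteryModel(
        pixels=np.column_stack([cols, rows]),
        columns=uniq.astype(int),
        col_means=col_means,
        diagnostics={"n_regions": n_regions},
    )


def fit_artery_line(
    model: ArteryModel, outlier_px: float = 5.0
) -> tuple[float, float]:
    """Ordinary least squares of per-column mean rows on columns.

    A single re-fit pass drops columns whose residual against the first
    fit exceeds ``outlier_px``: a handful of spuriously selected regions
    far from the artery (a cold-marker or silhouette region that slipped
    through the thresholds) would otherwise leverage the line away from
    the stripe. Artery columns themselves scatter well below a pixel.
    """
    if np.unique(model.columns).size < 2:
        raise FitError("need >= 2 distinct columns to fit the artery line")
    x = model.columns.astype(float)
    y = model.col_means
    slope, intercept = np.polyfit(x, y, 1)
    resid = np.abs(y - (slope * x + intercept))
    keep = resid <= outlier_px
    if keep.sum() >= 2 and keep.sum() < keep.size:
        slope, intercept = np.polyfit(x[keep], y[keep], 1)
        model.diagnostics["n_outlier_cols"] = int((~keep).sum())
    model.slope, model.intercept = float(slope), float(intercept)
    return model.slope, model.intercept


def _round_half_away(x: float) -> int:
    return int(np.sign(x) * np.floor(abs(x) + 0.5))


def locate_y(model: ArteryModel, x0: int, shape: tuple[int, int]) -> int:
    """GUAN row: the fitted artery line evaluated at the GUAN column.

    Rounded half-away-from-zero to a pixel row; the unrounded value is kept
    in the model diagnostics.
    """
    if model.slope is None or model.intercept is None:
        fit_artery_line(model)
    y_raw = model.slope * float(x0) + model.intercept
    model.diagnostics["y0_raw"] = float(y_raw)
    y0 = _round_half_away(y_raw)
    if not 0 <= y0 < shape[0]:
        raise LocalizationError(f"artery line gives row {y0} outside image")
    return y0
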