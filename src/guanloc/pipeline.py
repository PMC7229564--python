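"""End-to-end GUAN localization: orchestrates all pipeline stages."""

from __future__ import annotations

import logging

import numpy as np

from . import artery as artery_mod
from . import contour as contour_mod
from . import edges as edges_mod
from . import geometry as geometry_mod
from . import landmark as landmark_mod
from .config import PipelineConfig
from .errors import GuanlocError, StageError
from .io import GuanResult, ThermalImage

__all__ = ["locate", "detect_cold_spot"]

log = logging.getLogger("guanloc")


def locate(
    image: ThermalImage,
    config: PipelineConfig | None = None,
    crease_x_px: int | None = None,
) -> GuanResult:
    """Run the full pipeline on one thermal image.

    Stages: edge detection -> largest connected domain -> breakpoint
    connection (if needed) -> branch cutting -> single-valued outline ->
    Butterworth smoothing + curvature -> salient + finger-width recess rule
    (x0) -> region statistics + thresholds + artery pixel selection ->
    least-squares artery line (y0) -> optional pixel-to-mm mapping.

    ``crease_x_px`` supplies the wrist-crease reference column (from the
    aluminium-sheet marker); when present together with a configured camera
    geometry, the crease-to-GUAN distance in mm is reported.

    Deterministic for a fixed image and configuration. Any stage failure is
    re-raised as :class:`StageError` carrying the stage name.
    """
    cfg = config or PipelineConfig()
    diag: dict = {}

    def _stage(name, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except GuanlocError as exc:
            raise StageError(name, exc) from exc

    edge_map = _stage(
        "edges",
        edges_mod.detect_edges,
        image,
        sigma=cfg.edge.sigma,
        n_angles=cfg.edge.n_angles,
        threshold_quantile=cfg.edge.threshold_quantile,
        connection=cfg.edge.connection,
        noise_floor_mult=cfg.edge.noise_floor_mult,
    )
    _stage("edges", edges_mod.require_nonempty, edge_map)
    diag["n_edge_px"] = edge_map.count()

    component = _stage("contour", contour_mod.max_connected_domain, edge_map)
    if not component.spans_lateral_borders():
        component = _stage(
            "contour",
            contour_mod.connect_breakpoints,
            edge_map,
            component,
            search_range=cfg.contour.search_range,
        )
    component = _stage(
        "contour",
        contour_mod.cut_branches,
        component,
        max_spur_len=cfg.contour.max_spur_len,
    )
    outline = _stage(
        "contour", contour_mod.to_outline, component, side=cfg.contour.side
    )
    diag["outline_cols"] = [outline.col_start, outline.col_end]

    profile = _stage(
        "landmark",
        landmark_mod.curvature_profile,
        outline,
        spec=cfg.landmark.filter,
        side=cfg.contour.side,
        hand_side=cfg.landmark.hand_side,
    )
    salient = _stage("landmark", landmark_mod.find_salient, profile)
    diag["salient_col"] = salient
    x0 = _stage(
        "landmark",
        landmark_mod.locate_x,
        profile,
        window_px=cfg.landmark.window_px,
        scan=cfg.landmark.scan,
        slope_min=cfg.landmark.slope_min,
    )
    diag["x0"] = x0
    log.info("salient_col=%d x0=%d", salient, x0)

    stats = _stage(
        "artery", artery_mod.region_stats, image, edge_map, size=cfg.artery.region_size
    )
    thresholds = _stage(
        "artery",
        artery_mod.derive_thresholds,
        image,
        stats,
        method=cfg.artery.method,
        mean_pct=cfg.artery.mean_pct,
        std_pct=cfg.artery.std_pct,
    )
    diag["thresholds"] = [
        thresholds.mean_min,
        thresholds.mean_max,
        thresholds.std_min,
        thresholds.std_max,
    ]
    band = None
    if cfg.artery.band_px is not None:
        band = (x0 - cfg.artery.band_px, x0 + cfg.artery.band_px)
    # the artery is interior to the wrist: regions centred at or above the
    # extracted outline (plus margin) are silhouette, not artery
    row_min = np.zeros(image.shape[1])
    row_min[outline.columns] = outline.rows + cfg.artery.outline_margin_px
    model = _stage(
        "artery",
        artery_mod.select_artery_pixels,
        image,
        stats,
        thresholds,
        size=cfg.artery.region_size,
        band=band,
        row_min=row_min,
    )
    slope, intercept = _stage("artery", artery_mod.fit_artery_line, model)
    diag["artery_slope"] = slope
    diag["artery_intercept"] = intercept
    y0 = _stage("artery", artery_mod.locate_y, model, x0, image.shape)
    diag["y0_raw"] = model.diagnostics["y0_raw"]
    log.info("artery slope=%.4f intercept=%.2f y0=%d", slope, intercept, y0)

    result = GuanResult(
        x0_px=int(x0), y0_px=int(y0), crease_x_px=crease_x_px, diagnostics=diag
    )
    if cfg.geometry is not None:
        result = _stage(
            "geometry",
            geometry_mod.map_guan,
            result,
            cfg.geometry,
            tilt_axis=cfg.tilt_axis,
        )
    return result


def detect_cold_spot(
    image: ThermalImage, size: int = 6, edge_margin: int = 60, edge: str = "right"
) -> int:
    """Best-effort wrist-crease marker detector for real images.

    Returns the column of the darkest ``size``x``size`` mean block within
    ``edge_margin`` columns of the configured lateral edge. The synthetic
    experiments use the phantom's known crease instead; this helper is
    plumbing for real acquisitions where the aluminium sheet appears as a
    cold spot.
    """
    from scipy import ndimage

    arr = image.pixels
    h, w = arr.shape
    if edge == "right":
        sub = arr[:, w - edge_margin :]
        col0 = w - edge_margin
    else:
        sub = arr[:, :edge_margin]
        col0 = 0
    # score = surrounding-ring mean minus block mean: a cold marker sits
    # inside warm skin, whereas plain background is cold all around
    small = ndimage.uniform_filter(sub, size, mode="nearest")
    big = ndimage.uniform_filter(sub, 3 * size, mode="nearest")
    ring = (big * 9.0 - small) / 8.0
    score = ring - small
    _, c = np.unravel_index(np.argmax(score), score.shape)
    return int(col0 + c)
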