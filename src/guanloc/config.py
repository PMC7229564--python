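"""Pipeline configuration: defaults, YAML loading, strict key validation."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields

import yaml

from .errors import ParameterError
from .geometry import CameraGeometry
from .landmark import FilterSpec

__all__ = [
    "EdgeConfig",
    "ContourConfig",
    "LandmarkConfig",
    "ArteryConfig",
    "PipelineConfig",
    "load_config",
    "load_geometry",
]


@dataclass
class EdgeConfig:
    sigma: float = 2.0
    n_angles: int = 8
    threshold_quantile: float = 0.70
    connection: str = "compact"
    noise_floor_mult: float = 8.0


@dataclass
class ContourConfig:
    max_spur_len: int = 15
    side: str = "upper"
    search_range: int = 2


@dataclass
class LandmarkConfig:
    window_px: int = 100
    hand_side: str = "right"
    scan: str = "nearest"
    slope_min: float = 0.02
    filter: FilterSpec = field(default_factory=FilterSpec)


@dataclass
class ArteryConfig:
    region_size: int = 10
    method: str = "otsu"
    mean_pct: tuple[float, float] = (70.0, 99.5)
    std_pct: tuple[float, float] = (0.0, 60.0)
    band_px: int | None = 60
    outline_margin_px: int = 15


@dataclass
class PipelineConfig:
    edge: EdgeConfig = field(default_factory=EdgeConfig)
    contour: ContourConfig = field(default_factory=ContourConfig)
    landmark: LandmarkConfig = field(default_factory=LandmarkConfig)
    artery: ArteryConfig = field(default_factory=ArteryConfig)
    geometry: CameraGeometry | None = None
    tilt_axis: str = "cols"
    log_level: str = "INFO"

    def to_dict(self) -> dict:
        return asdict(self)


_FILTER_KEYS = {
    "fs": "sample_rate",
    "fpass": "passband_hz",
    "fstop": "stopband_hz",
    "ripple_db": "passband_ripple_db",
    "atten_db": "stopband_atten_db",
}


def _build(cls, data: dict, where: str):
    known = {f.name: f for f in fields(cls)}
    unknown = set(data) - set(known)
    if unknown:
        raise ParameterError(f"unknown config key(s) in {where}: {sorted(unknown)}")
    return cls(**data)


def load_config(data: dict | str | None) -> PipelineConfig:
    """Build a PipelineConfig from a dict or YAML path; unknown keys rejected.

    Expected layout mirrors the dataclasses::

        edge: {sigma: 2.0, ...}
        landmark: {window_px: 100, filter: {fs: 70, fpass: 2, ...}}
        geometry: {theta_deg: 20, ...}
    """
    if data is None:
        return PipelineConfig()
    if isinstance(data, str):
        with open(data) as fh:
            data = yaml.safe_load(fh) or {}
    data = dict(data)
    out = PipelineConfig()
    sections = {
        "edge": (EdgeConfig, "edge"),
        "contour": (ContourConfig, "contour"),
        "artery": (ArteryConfig, "artery"),
    }
    for key, (cls, name) in sections.items():
        if key in data:
            sub = dict(data.pop(key))
            if key == "artery":
                for pct in ("mean_pct", "std_pct"):
                    if pct in sub:
                        sub[pct] = tuple(sub[pct])
            setattr(out, name, _build(cls, sub, name))
    if "landmark" in data:
        sub = dict(data.pop("landmark"))
        if "filter" in sub:
            fdata = {
                _FILTER_KEYS.get(k, k): v for k, v in dict(sub.pop("filter")).items()
            }
            sub["filter"] = _build(FilterSpec, fdata, "landmark.filter")
        out.landmark = _build(LandmarkConfig, sub, "landmark")
    if "geometry" in data:
        geo = data.pop("geometry")
        if geo is not None:
            out.geometry = _build(CameraGeometry, dict(geo), "geometry")
    for key in ("tilt_axis", "log_level"):
        if key in data:
            setattr(out, key, data.pop(key))
    if data:
        raise ParameterError(f"unknown top-level config key(s): {sorted(data)}")
    return out


def load_geometry(path: str) -> CameraGeometry:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if "geometry" in data:
        data = data["geometry"]
    return _build(CameraGeometry, dict(data), "geometry")
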