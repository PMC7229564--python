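"""Image and result I/O.

Defines the core :class:`ThermalImage` container and readers/writers for the
formats the pipeline touches: grayscale TIFF/PNG (8/16-bit), plain-text CSV
temperature matrices, JSON results, and annotated PNG renderings.

Conventions
-----------
* Pixel coordinates are 0-based ``(column, row)``; row index increases
  downward, column index increases rightward.
* Readers never rescale intensities: integer images are cast to float with
  their raw values preserved.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import tifffile

from .errors import InputFormatError, LocalizationError, ValidationError

MIN_SIZE = 32  # minimum working height/width of the pipeline, in pixels

__all__ = [
    "ThermalImage",
    "GuanResult",
    "read_image",
    "write_image",
    "write_result",
    "read_result",
    "write_annotated",
]


@dataclass
class ThermalImage:
    """A single-channel thermal image.

    Parameters
    ----------
    pixels : ndarray of shape (height, width)
        Non-negative intensity values in arbitrary thermal units (raw sensor
        counts or temperature-like units). Stored as float64.
    source : str
        Free-text provenance (file path, "phantom", ...).
    """

    pixels: np.ndarray
    source: str = ""

    def __post_init__(self) -> None:
        arr = np.asarray(self.pixels, dtype=np.float64)
        if arr.ndim != 2:
            raise ValidationError(f"expected a 2-D grid, got ndim={arr.ndim}")
        if arr.shape[0] < MIN_SIZE or arr.shape[1] < MIN_SIZE:
            raise ValidationError(
                f"image {arr.shape} smaller than minimum working size "
                f"{MIN_SIZE}x{MIN_SIZE}"
            )
        if not np.all(np.isfinite(arr)):
            raise ValidationError("image contains NaN or Inf values")
        self.pixels = arr

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass
class GuanResult:
    """Located GUAN position, in pixels and (optionally) in millimetres.

    Optional fields are ``None`` when the corresponding information is not
    available (no camera geometry configured, no crease reference).
    """

    x0_px: int
    y0_px: int
    x_world_mm: float | None = None
    y_world_mm: float | None = None
    crease_x_px: int | None = None
    x_distance_mm: float | None = None
    diagnostics: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        """Serializable dict; optional fields omitted (never null-filled)."""
        out: dict = {"x0_px": int(self.x0_px), "y0_px": int(self.y0_px)}
        for key in ("x_world_mm", "y_world_mm", "crease_x_px", "x_distance_mm"):
            val = getattr(self, key)
            if val is not None:
                out[key] = val
        if self.diagnostics:
            out["diagnostics"] = self.diagnostics
        return out

    @classmethod
    def from_dict(cls, d: dict) -> "GuanResult":
        return cls(
            x0_px=int(d["x0_px"]),
            y0_px=int(d["y0_px"]),
            x_world_mm=d.get("x_world_mm"),
            y_world_mm=d.get("y_world_mm"),
            crease_x_px=d.get("crease_x_px"),
            x_distance_mm=d.get("x_distance_mm"),
            diagnostics=d.get("diagnostics", {}),
        )


def _infer_kind(path: Path) -> str:
    suffix = path.suffix.lower()
    if suffix in (".tif", ".tiff"):
        return "tiff"
    if suffix == ".png":
        return "png"
    if suffix in (".csv", ".txt", ".dat"):
        return "csv"
    raise InputFormatError(f"cannot infer image kind from suffix {suffix!r}")


def _read_csv_matrix(path: Path) -> np.ndarray:
    with open(path) as fh:
        first = fh.readline()
    delimiter = "," if "," in first else None  # None = any whitespace
    try:
        arr = np.loadtxt(path, delimiter=delimiter, ndmin=2)
    except Exception as exc:  # noqa: BLE001 - report as format error
        raise InputFormatError(f"cannot parse CSV matrix {path}: {exc}") from exc
    if not np.all(np.isfinite(arr)):
        raise ValidationError(f"CSV matrix {path} contains NaN/Inf")
    return arr


def read_image(path, kind: str = "auto", convert_rgb: bool = False) -> ThermalImage:
    """Read a thermal image from TIFF, PNG, or a CSV temperature matrix.

    Multichannel images are rejected unless ``convert_rgb=True``, in which
    case they are reduced by ITU-R 601 luminance with a warning.
    """
    path = Path(path)
    if not path.exists():
        raise InputFormatError(f"no such file: {path}")
    if kind == "auto":
        kind = _infer_kind(path)
    if kind == "csv":
        arr = _read_csv_matrix(path)
    elif kind in ("tiff", "png"):
        try:
            arr = tifffile.imread(path) if kind == "tiff" else iio.imread(path)
        except Exception as exc:  # noqa: BLE001
            raise InputFormatError(f"cannot read {kind} file {path}: {exc}") from exc
        arr = np.asarray(arr)
        if arr.ndim == 3:
            if not convert_rgb:
                raise InputFormatError(
                    f"{path} has {arr.shape[-1]} channels; pass convert_rgb=True "
                    "to reduce by luminance"
                )
            warnings.warn(
                f"converting multichannel image {path} to luminance",
                stacklevel=2,
            )
            arr = (
                0.299 * arr[..., 0] + 0.587 * arr[..., 1] + 0.114 * arr[..., 2]
            )
        elif arr.ndim != 2:
            raise InputFormatError(f"{path}: unsupported dimensionality {arr.ndim}")
    else:
        raise InputFormatError(f"unknown image kind {kind!r}")
    return ThermalImage(arr.astype(np.float64), source=str(path))


def write_image(image: ThermalImage, path, kind: str = "auto") -> None:
    """Write a thermal image.

    Integer-valued images in [0, 65535] are written losslessly as 16-bit
    TIFF/PNG; CSV preserves full float precision.
    """
    path = Path(path)
    if kind == "auto":
        kind = _infer_kind(path)
    arr = image.pixels
    if kind == "csv":
        np.savetxt(path, arr, delimiter=",", fmt="%.12g")
        return
    integral = np.all(arr == np.round(arr)) and arr.min() >= 0 and arr.max() <= 65535
    if not integral:
        raise InputFormatError(
            "TIFF/PNG output requires integer values in [0, 65535]; "
            "use CSV for float matrices"
        )
    data = arr.astype(np.uint16)
    if kind == "tiff":
        tifffile.imwrite(path, data)
    elif kind == "png":
        iio.imwrite(path, data)
    else:
        raise InputFormatError(f"unknown image kind {kind!r}")


def write_result(result: GuanResult, path) -> None:
    """Serialize a :class:`GuanResult` to JSON at full precision."""
    path = Path(path)
    try:
        with open(path, "w") as fh:
            json.dump(result.to_dict(), fh, indent=2)
            fh.write("\n")
    except OSError as exc:
        raise InputFormatError(f"cannot write result to {path}: {exc}") from exc


def read_result(path) -> GuanResult:
    with open(path) as fh:
        return GuanResult.from_dict(json.load(fh))


def write_annotated(image: ThermalImage, result: GuanResult, path) -> None:
    """Render an 8-bit annotation: vertical line at x0 and a cross at GUAN.

    The input image is not modified. The rendering is min-max scaled to
    8-bit grayscale, promoted to RGB, and saved as PNG with the x0 column
    marked by a full-height line and the GUAN position by a cross.
    """
    x0, y0 = int(result.x0_px), int(result.y0_px)
    h, w = image.shape
    if not (0 <= x0 < w and 0 <= y0 < h):
        raise LocalizationError(f"GUAN ({x0}, {y0}) outside image {w}x{h}")
    arr = image.pixels
    lo, hi = float(arr.min()), float(arr.max())
    scale = 255.0 / (hi - lo) if hi > lo else 0.0
    gray = ((arr - lo) * scale).astype(np.uint8)
    rgb = np.stack([gray] * 3, axis=-1)
    rgb[:, x0] = (255, 0, 0)  # vertical line spanning full height
    half = 6
    rgb[y0, max(0, x0 - half) : min(w, x0 + half + 1)] = (0, 255, 0)
    rgb[max(0, y0 - half) : min(h, y0 + half + 1), x0] = (0, 255, 0)
    if result.crease_x_px is not None and 0 <= int(result.crease_x_px) < w:
        rgb[:, int(result.crease_x_px)] = (0, 128, 255)
    iio.imwrite(Path(path), rgb)
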