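"""Image and ROI input/output plus ROI geometry.

Fluorescence micrographs are read as RGB rasters and split into channel
planes; the blue channel carries the Pacific Blue emission and is the only
channel used for quantitation.  Regions of interest (droplet outlines,
crater outlines, background patches) are polygons or ellipses in pixel
coordinates, stored in a small JSON dialect, one file per image.

Coordinate convention: 0-based, x rightward, y downward, and the centre of
pixel ``(0, 0)`` sits at coordinate ``(0.0, 0.0)``.  A pixel belongs to an
ROI iff its centre lies inside the shape; centres exactly on the boundary
are included on the top/left edge and excluded on the bottom/right edge so
that adjacent ROIs tile without overlap.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Sequence, Union

import numpy as np
import shapely
from shapely.geometry import Polygon as _ShapelyPolygon

__all__ = [
    "ImagePlane",
    "PolygonShape",
    "EllipseShape",
    "Roi",
    "read_rgb_image",
    "write_rgb_image",
    "blue_channel",
    "roi_pixel_mask",
    "roi_area_um2",
    "roi_mean_intensity",
    "read_roi_file",
    "write_roi_file",
]

# Half-open tie-break: testing the centre shifted by +eps in x and +y makes
# top/left boundary centres land strictly inside and bottom/right ones
# strictly outside, deterministically.
_TIE_EPS = 1e-9

Channel = Literal["red", "green", "blue", "mono"]
HumidityState = Literal["dry", "humid", "brightfield"]


@dataclass
class ImagePlane:
    """A single-channel pixel grid with its acquisition metadata.

    Parameters
    ----------
    pixels
        2-D array of non-negative integer counts, shape ``(height, width)``.
    bit_depth
        8 or 16; every pixel must lie in ``[0, 2**bit_depth - 1]``.
    channel
        Which RGB component this plane is, or ``"mono"`` for grayscale.
    exposure_s
        Exposure time in seconds (the ``s`` of the integrated-intensity
        formula), strictly positive.
    pixel_size_um
        Micrometres per pixel for the objective used, strictly positive.
    humidity_state
        Whether the image was taken dry (< ~10 % RH), humidified (70 % RH)
        or under oblique white light (``"brightfield"``).
    """

    pixels: np.ndarray
    bit_depth: int
    channel: Channel
    exposure_s: float
    pixel_size_um: float
    humidity_state: HumidityState = "humid"

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise ValueError("pixels must be a 2-D array")
        if self.bit_depth not in (8, 16):
            raise ValueError(f"bit_depth must be 8 or 16, got {self.bit_depth}")
        if self.pixels.size and (
            self.pixels.min() < 0 or self.pixels.max() > self.max_count
        ):
            raise ValueError(
                f"pixel values must lie in [0, {self.max_count}] for "
                f"{self.bit_depth}-bit data"
            )
        if not self.exposure_s > 0:
            raise ValueError(f"exposure_s must be > 0, got {self.exposure_s}")
        if not self.pixel_size_um > 0:
            raise ValueError(f"pixel_size_um must be > 0, got {self.pixel_size_um}")

    @property
    def height_px(self) -> int:
        return self.pixels.shape[0]

    @property
    def width_px(self) -> int:
        return self.pixels.shape[1]

    @property
    def max_count(self) -> int:
        """Largest representable count, ``2**bit_depth - 1``."""
        return (1 << self.bit_depth) - 1


@dataclass
class PolygonShape:
    """Simple polygon, ordered vertices in pixel coordinates."""

    vertices: np.ndarray  # (n, 2) float, columns (x, y)

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 2:
            raise ValueError("vertices must be an (n, 2) array of (x, y)")
        if len(self.vertices) < 3:
            raise ValueError("polygon needs at least 3 vertices")
        poly = self.as_shapely()
        if not poly.is_valid:
            raise ValueError("polygon must be simple (no self-intersection)")
        if poly.area <= 0:
            raise ValueError("polygon has zero area")

    def as_shapely(self) -> _ShapelyPolygon:
        return _ShapelyPolygon(self.vertices)

    def area_px2(self) -> float:
        # Shoelace formula.
        x = self.vertices[:, 0]
        y = self.vertices[:, 1]
        return 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(np.roll(x, -1), y))


@dataclass
class EllipseShape:
    """Ellipse: centre, semi-axes and orientation in pixel coordinates.

    ``angle_deg`` rotates the semi-major axis counter-clockwise from +x
    (with y pointing down this appears clockwise on screen).
    """

    cx: float
    cy: float
    a: float  # semi-major, px
    b: float  # semi-minor, px
    angle_deg: float = 0.0

    def __post_init__(self) -> None:
        if not (self.a >= self.b > 0):
            raise ValueError(
                f"need semi-major >= semi-minor > 0, got a={self.a}, b={self.b}"
            )

    def area_px2(self) -> float:
        return math.pi * self.a * self.b


Shape = Union[PolygonShape, EllipseShape]


@dataclass
class Roi:
    """A labelled region with a signal or background role."""

    label: str
    shape: Shape
    role: Literal["signal", "background"]

    def __post_init__(self) -> None:
        if self.role not in ("signal", "background"):
            raise ValueError(f"role must be 'signal' or 'background', got {self.role!r}")


# ---------------------------------------------------------------------------
# image I/O


def _plane_dtype(bit_depth: int):
    return np.uint8 if bit_depth == 8 else np.uint16


def read_rgb_image(
    path: str | Path,
    exposure_s: float,
    pixel_size_um: float,
    humidity_state: HumidityState = "humid",
) -> list[ImagePlane]:
    """Read an RGB (or grayscale) raster and split it into channel planes.

    Returns three planes tagged red/green/blue for an RGB image, or a single
    ``mono`` plane for grayscale input.  TIFF and PNG, 8- or 16-bit.
    """
    import imageio.v3 as iio

    if not exposure_s > 0:
        raise ValueError(f"exposure_s must be > 0, got {exposure_s}")
    if not pixel_size_um > 0:
        raise ValueError(f"pixel_size_um must be > 0, got {pixel_size_um}")
    try:
        arr = iio.imread(Path(path))
    except Exception as exc:  # pragma: no cover - message formatting only
        raise ValueError(f"unreadable image file {path!r}: {exc}") from exc

    if arr.dtype == np.uint8:
        bit_depth = 8
    elif arr.dtype == np.uint16:
        bit_depth = 16
    else:
        raise ValueError(
            f"unsupported bit depth: dtype {arr.dtype} in {path!r} "
            "(8- or 16-bit unsigned integer required)"
        )

    meta = dict(
        bit_depth=bit_depth,
        exposure_s=exposure_s,
        pixel_size_um=pixel_size_um,
        humidity_state=humidity_state,
    )
    if arr.ndim == 2:
        return [ImagePlane(arr, channel="mono", **meta)]
    if arr.ndim == 3 and arr.shape[2] in (3, 4):
        names: list[Channel] = ["red", "green", "blue"]
        return [ImagePlane(arr[:, :, i], channel=names[i], **meta) for i in range(3)]
    raise ValueError(
        f"unsupported image layout {arr.shape} in {path!r}; expected HxW or HxWx3"
    )


def write_rgb_image(path: str | Path, planes: Sequence[ImagePlane]) -> None:
    """Write channel planes back to a TIFF/PNG raster (inverse of read)."""
    import imageio.v3 as iio

    path = Path(path)
    if len(planes) == 1:
        arr = planes[0].pixels.astype(_plane_dtype(planes[0].bit_depth))
    else:
        by_channel = {p.channel: p for p in planes}
        try:
            stack = [by_channel[c].pixels for c in ("red", "green", "blue")]
        except KeyError as exc:
            raise ValueError(f"missing channel {exc.args[0]!r} for RGB write") from exc
        arr = np.stack(stack, axis=-1).astype(_plane_dtype(planes[0].bit_depth))
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        tifffile.imwrite(path, arr)
    else:
        iio.imwrite(path, arr)


def blue_channel(planes: Sequence[ImagePlane]) -> ImagePlane:
    """Select the plane carrying the Pacific Blue emission.

    The blue plane of an RGB split, or the single mono plane for grayscale
    input.
    """
    for plane in planes:
        if plane.channel == "blue":
            return plane
    if len(planes) == 1 and planes[0].channel == "mono":
        return planes[0]
    raise ValueError("no blue or mono plane present")


# ---------------------------------------------------------------------------
# ROI geometry


def roi_pixel_mask(roi: Roi, width_px: int, height_px: int) -> np.ndarray:
    """Boolean mask of pixels whose centres lie inside the ROI.

    Centre-in convention with the half-open top/left tie-break; the mask is
    clipped to the image bounds.  Raises if no pixel centre falls inside.
    """
    if width_px <= 0 or height_px <= 0:
        raise ValueError("image dimensions must be positive")
    shape = roi.shape
    if isinstance(shape, EllipseShape):
        xmin = shape.cx - shape.a
        xmax = shape.cx + shape.a
        ymin = shape.cy - shape.a
        ymax = shape.cy + shape.a
    else:
        xmin, ymin = shape.vertices.min(axis=0)
        xmax, ymax = shape.vertices.max(axis=0)
    # candidate pixel centres restricted to the bounding box, clipped to image
    x0 = max(int(math.floor(xmin)) - 1, 0)
    x1 = min(int(math.ceil(xmax)) + 1, width_px - 1)
    y0 = max(int(math.floor(ymin)) - 1, 0)
    y1 = min(int(math.ceil(ymax)) + 1, height_px - 1)
    mask = np.zeros((height_px, width_px), dtype=bool)
    if x1 < x0 or y1 < y0:
        raise ValueError(f"ROI {roi.label!r} lies fully outside the image")
    xs = np.arange(x0, x1 + 1, dtype=float) + _TIE_EPS
    ys = np.arange(y0, y1 + 1, dtype=float) + _TIE_EPS
    gx, gy = np.meshgrid(xs, ys)
    if isinstance(shape, EllipseShape):
        theta = math.radians(shape.angle_deg)
        dx = gx - shape.cx
        dy = gy - shape.cy
        u = dx * math.cos(theta) + dy * math.sin(theta)
        v = -dx * math.sin(theta) + dy * math.cos(theta)
        inside = (u / shape.a) ** 2 + (v / shape.b) ** 2 < 1.0
    else:
        inside = shapely.contains_xy(
            shape.as_shapely(), gx.ravel(), gy.ravel()
        ).reshape(gx.shape)
    mask[y0 : y1 + 1, x0 : x1 + 1] = inside
    if not mask.any():
        raise ValueError(
            f"ROI {roi.label!r} contains no pixel centres within the image"
        )
    return mask


def roi_area_um2(roi: Roi, pixel_size_um: float) -> float:
    """Geometric ROI area in square micrometres.

    Shoelace for polygons, pi*a*b for ellipses, times ``pixel_size_um**2``.
    This continuous area is the ``A`` of the integrated-intensity formula;
    the pixel mask is used only for intensity means.
    """
    if not pixel_size_um > 0:
        raise ValueError(f"pixel_size_um must be > 0, got {pixel_size_um}")
    area_px2 = roi.shape.area_px2()
    if area_px2 <= 0:
        raise ValueError(f"ROI {roi.label!r} has degenerate (zero) area")
    return area_px2 * pixel_size_um**2


def roi_mean_intensity(plane: ImagePlane, roi: Roi) -> float:
    """Arithmetic mean of pixel counts inside the ROI mask."""
    mask = roi_pixel_mask(roi, plane.width_px, plane.height_px)
    return float(plane.pixels[mask].mean())


# ---------------------------------------------------------------------------
# ROI JSON dialect


def _shape_to_json(shape: Shape) -> dict:
    if isinstance(shape, PolygonShape):
        return {"type": "polygon", "vertices": shape.vertices.tolist()}
    return {
        "type": "ellipse",
        "cx": shape.cx,
        "cy": shape.cy,
        "a": shape.a,
        "b": shape.b,
        "angle_deg": shape.angle_deg,
    }


def _shape_from_json(obj: dict) -> Shape:
    try:
        kind = obj["type"]
    except KeyError:
        raise ValueError("ROI shape is missing the 'type' field") from None
    if kind == "polygon":
        if "vertices" not in obj:
            raise ValueError("polygon shape is missing the 'vertices' field")
        return PolygonShape(np.asarray(obj["vertices"], dtype=float))
    if kind == "ellipse":
        missing = [k for k in ("cx", "cy", "a", "b") if k not in obj]
        if missing:
            raise ValueError(f"ellipse shape is missing field(s) {missing}")
        return EllipseShape(
            cx=float(obj["cx"]),
            cy=float(obj["cy"]),
            a=float(obj["a"]),
            b=float(obj["b"]),
            angle_deg=float(obj.get("angle_deg", 0.0)),
        )
    raise ValueError(f"unknown ROI shape type {kind!r}")


def write_roi_file(rois: Sequence[Roi], path: str | Path) -> None:
    """Write ROIs to the JSON dialect (one file per image)."""
    doc = {
        "rois": [
            {"label": r.label, "role": r.role, "shape": _shape_to_json(r.shape)}
            for r in rois
        ]
    }
    Path(path).write_text(json.dumps(doc, indent=1))


def read_roi_file(path: str | Path) -> list[Roi]:
    """Read ROIs back from the JSON dialect, validating every field."""
    try:
        doc = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise ValueError(f"ROI file {path!r} is not valid JSON: {exc}") from exc
    if "rois" not in doc:
        raise ValueError(f"ROI file {path!r} is missing the top-level 'rois' field")
    rois = []
    for i, entry in enumerate(doc["rois"]):
        for fld in ("label", "role", "shape"):
            if fld not in entry:
                raise ValueError(f"ROI #{i} in {path!r} is missing the {fld!r} field")
        rois.append(
            Roi(
                label=str(entry["label"]),
                role=entry["role"],
                shape=_shape_from_json(entry["shape"]),
            )
        )
    return rois
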