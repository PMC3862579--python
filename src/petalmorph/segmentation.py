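"""Binary segmentation of flower/petal photographs and outline tracing.

Flowers and flattened petals are photographed or scanned as bright objects on
a dark background; the red channel gives the clearest contrast, so
segmentation thresholds the red channel (automatically by Otsu's method, or
at a fixed user-supplied level), keeps the largest connected component with
interior holes filled, and traces its boundary as a closed polygon along
pixel corners ("crack" boundary).  All downstream geometry is computed on
that polygon in centimetre coordinates.

Coordinate convention: x = column * pixel_size, y = row * pixel_size, i.e. y
increases *downward* as in the image.  Contours are oriented so that their
shoelace signed area is positive in this frame, and that orientation is what
the rest of the package calls counterclockwise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu

__all__ = [
    "RasterImage",
    "BinaryMask",
    "Contour",
    "EmptySegmentationError",
    "ObjectTooSmallError",
    "calibrate",
    "binarize_red_channel",
    "extract_main_object",
    "trace_contour",
    "simplify_contour",
    "segment_image",
]

VIEW_LABELS = ("top", "side", "bottom", "petal_scan")


class EmptySegmentationError(ValueError):
    """Raised when thresholding yields no foreground pixels."""


class ObjectTooSmallError(ValueError):
    """Raised when the largest connected component is below the minimum area."""


@dataclass
class RasterImage:
    """An RGB photograph or scan of a single flower or petal.

    Parameters
    ----------
    pixels : (H, W, 3) uint8 array
    dpi : scanner resolution (dots per inch), if known.  Camera images of
        whole flowers have no dpi; supply ``pixel_size_cm`` to the
        segmentation functions instead.
    view_label : one of ``top``, ``side``, ``bottom``, ``petal_scan``.
    name : optional identifier used in error messages.
    """

    pixels: np.ndarray
    dpi: float | None = None
    view_label: str = "petal_scan"
    name: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ValueError("RasterImage requires an H x W x 3 array")
        if self.pixels.shape[0] < 1 or self.pixels.shape[1] < 1:
            raise ValueError("empty image")
        if self.view_label not in VIEW_LABELS:
            raise ValueError(f"unknown view label {self.view_label!r}")

    @property
    def red(self) -> np.ndarray:
        return self.pixels[:, :, 0]


@dataclass
class BinaryMask:
    """Foreground/background raster with physical pixel calibration."""

    pixels: np.ndarray
    pixel_size_cm: float
    calibrated: bool = True  # False => pixel_size_cm is a nominal unit ("relative units")

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=bool)
        if self.pixel_size_cm <= 0:
            raise ValueError("pixel_size_cm must be positive")

    @property
    def area_px(self) -> int:
        return int(self.pixels.sum())

    @property
    def area_cm2(self) -> float:
        return self.area_px * self.pixel_size_cm**2


@dataclass
class Contour:
    """Closed boundary polygon in cm, positively oriented (y-down frame).

    ``points`` holds the vertices once (closure to the first point is
    implied).  ``pixel_size_cm`` is carried along from the source mask when
    the contour was traced from a raster; it is None for analytic polygons.
    """

    points: np.ndarray
    pixel_size_cm: float | None = None
    touches_border: bool = field(default=False, compare=False)

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2 or len(pts) < 3:
            raise ValueError("a contour needs at least 3 (x, y) points")
        # drop an explicit closing point and any zero-length edges
        if np.allclose(pts[0], pts[-1]):
            pts = pts[:-1]
        keep = np.any(pts != np.roll(pts, 1, axis=0), axis=1)
        pts = pts[keep]
        if len(pts) < 3:
            raise ValueError("degenerate contour")
        area = _signed_area(pts)
        if area == 0.0:
            raise ValueError("degenerate contour: zero enclosed area")
        if area < 0:
            pts = pts[::-1]
        self.points = pts

    @property
    def signed_area(self) -> float:
        return _signed_area(self.points)

    def perimeter(self) -> float:
        d = np.diff(np.vstack([self.points, self.points[:1]]), axis=0)
        return float(np.hypot(d[:, 0], d[:, 1]).sum())


def _signed_area(pts: np.ndarray) -> float:
    x, y = pts[:, 0], pts[:, 1]
    return 0.5 * float(np.dot(x, np.roll(y, -1)) - np.dot(np.roll(x, -1), y))


def calibrate(dpi: float) -> float:
    """Centimetres per pixel edge for a scan at the given dpi (2.54 / dpi)."""
    if dpi is None or dpi <= 0:
        raise ValueError("dpi must be positive for calibration")
    return 2.54 / dpi


def binarize_red_channel(
    img: RasterImage,
    threshold: int | None = None,
    pixel_size_cm: float | None = None,
) -> BinaryMask:
    """Threshold the red channel: foreground = red value > threshold.

    When ``threshold`` is None it is chosen automatically by Otsu's method on
    the red-channel histogram.  Calibration comes from the image dpi when
    present, otherwise from ``pixel_size_cm``; camera images with neither are
    measured in relative units (pixel_size_cm = 1, flagged uncalibrated).
    """
    red = img.red
    if threshold is None:
        if red.min() == red.max():
            raise EmptySegmentationError(
                f"empty segmentation: uniform red channel in {img.name or 'image'}"
            )
        threshold = threshold_otsu(red)
    fg = red > threshold
    if not fg.any():
        raise EmptySegmentationError(
            f"empty segmentation: no red-channel pixels above {threshold} "
            f"in {img.name or 'image'}"
        )
    if img.dpi is not None:
        return BinaryMask(fg, calibrate(img.dpi))
    if pixel_size_cm is not None:
        return BinaryMask(fg, pixel_size_cm)
    warnings.warn(
        f"{img.name or 'image'}: no dpi or cm-per-pixel supplied; "
        "areas and lengths are in relative units",
        stacklevel=2,
    )
    return BinaryMask(fg, 1.0, calibrated=False)


def extract_main_object(mask: BinaryMask, min_area_px: int = 50) -> BinaryMask:
    """Keep the largest 8-connected component and fill its interior holes.

    Components tied for the largest area are disambiguated by the row-major
    position of their first pixel (top-most, then left-most, wins).
    """
    if not mask.pixels.any():
        raise EmptySegmentationError("empty segmentation: mask has no foreground")
    labels, n = ndimage.label(mask.pixels, structure=np.ones((3, 3), dtype=int))
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
    order = np.argsort(-sizes, kind="stable")  # stable: row-major first-pixel tie-break
    # label ids are assigned in row-major order of first occurrence, so among
    # equal sizes the smaller label id is the earlier component
    best = int(order[0]) + 1
    if sizes[best - 1] < min_area_px:
        raise ObjectTooSmallError(
            f"object too small: largest component {int(sizes[best - 1])} px "
            f"< min_area_px={min_area_px}"
        )
    keep = labels == best
    keep = ndimage.binary_fill_holes(keep)
    return BinaryMask(keep, mask.pixel_size_cm, calibrated=mask.calibrated)


# crack-walk turn tables: directions are (dr, dc) steps between pixel corners
_LEFT = {(0, 1): (-1, 0), (1, 0): (0, 1), (0, -1): (1, 0), (-1, 0): (0, -1)}
_RIGHT = {v: k for k, v in _LEFT.items()}


def trace_contour(mask: BinaryMask) -> Contour:
    """Trace the crack boundary of the (single) filled component.

    The boundary runs along pixel corners; vertex coordinates are pixel-corner
    positions (origin at the image top-left, y down) converted to cm.  The
    shoelace area of the returned polygon equals the pixel count exactly.
    Consecutive collinear steps are merged.  A component touching the image
    border is traced but flagged (possibly cropped object).
    """
    m = mask.pixels
    if not m.any():
        raise EmptySegmentationError("empty segmentation: cannot trace empty mask")
    touches = bool(m[0, :].any() or m[-1, :].any() or m[:, 0].any() or m[:, -1].any())
    if touches:
        warnings.warn("object touches the image border; contour may be cropped",
                      stacklevel=2)

    H, W = m.shape
    pad = np.zeros((H + 2, W + 2), dtype=bool)
    pad[1:-1, 1:-1] = m

    rs, cs = np.nonzero(m)
    r0 = int(rs[0])
    c0 = int(cs[rs == r0].min())
    start = (r0, c0)  # top-left corner of the first foreground pixel
    pos = start
    d = (0, 1)
    verts: list[tuple[int, int]] = [start]
    max_steps = 8 * (H + 2) * (W + 2)
    steps = 0
    while True:
        # the two pixels flanking the edge ahead of `pos` along direction d;
        # the walk keeps foreground on its right-hand side
        r, c = pos
        if d == (0, 1):
            a = pad[r, c + 1]          # left of travel  (r-1, c)
            b = pad[r + 1, c + 1]      # right of travel (r, c)
        elif d == (1, 0):
            a = pad[r + 1, c + 1]      # (r, c)
            b = pad[r + 1, c]          # (r, c-1)
        elif d == (0, -1):
            a = pad[r + 1, c]          # (r, c-1)
            b = pad[r, c]              # (r-1, c-1)
        else:
            a = pad[r, c]              # (r-1, c-1)
            b = pad[r, c + 1]          # (r-1, c)
        if b and not a:
            nd = d
        elif a and b:
            nd = _LEFT[d]
        elif not a and not b:
            nd = _RIGHT[d]
        else:  # a and not b: pinch corner between 8-connected diagonal pixels
            nd = _LEFT[d]
        if nd != d:
            if verts[-1] != pos:
                verts.append(pos)
            d = nd
            continue
        pos = (r + d[0], c + d[1])
        steps += 1
        if pos == start:
            break
        if steps > max_steps:  # pragma: no cover - defensive
            raise RuntimeError("boundary trace failed to close")

    s = mask.pixel_size_cm
    pts = np.array([(c * s, r * s) for r, c in verts], dtype=float)
    return Contour(pts, pixel_size_cm=s, touches_border=touches)


def simplify_contour(c: Contour, tolerance_px: float = 1.4) -> Contour:
    """Douglas-Peucker simplification of a raster-traced contour.

    Removes the staircase quantization of the crack boundary so that polygon
    perimeter estimates smooth outlines accurately (raw crack perimeters
    overestimate smooth curves by up to 4/pi).  Exact on axis-aligned
    rectangles.  Tolerance is in pixels; for analytic contours (no pixel
    size) it is interpreted in cm.
    """
    from shapely.geometry import Polygon as _ShPolygon

    tol = tolerance_px * (c.pixel_size_cm or 1.0)
    poly = _ShPolygon(c.points).simplify(tol, preserve_topology=True)
    pts = np.asarray(poly.exterior.coords)[:-1]
    if len(pts) < 3:  # pragma: no cover - tiny objects
        return c
    return Contour(pts, pixel_size_cm=c.pixel_size_cm, touches_border=c.touches_border)


def segment_image(
    img: RasterImage,
    threshold: int | None = None,
    pixel_size_cm: float | None = None,
    min_area_px: int = 50,
) -> tuple[BinaryMask, Contour]:
    """Full segmentation chain: threshold, keep main object, trace contour."""
    mask = binarize_red_channel(img, threshold=threshold, pixel_size_cm=pixel_size_cm)
    mask = extract_main_object(mask, min_area_px=min_area_px)
    return mask, trace_contour(mask)
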