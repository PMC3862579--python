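"""Shape descriptors for segmented flowers and petals.

The descriptor set follows standard image-analysis practice for corolla and
petal outlines: object area and perimeter, major/minor chord lengths of the
moments-equivalent ("best fitting") ellipse, area and perimeter of the convex
hull, and three dimensionless shape factors derived from them:

* aspect ratio  = major chord / minor chord  (1 for a circle),
* solidity      = area / hull area           (1 for convex objects),
* convexity     = hull perimeter / perimeter (1 for convex outlines,
  decreasing with marginal serration — the serration descriptor).

Descriptors carry the conventional flower/petal mnemonics (FA, FP, FEM, FEN,
FHA, FHP, FAR, FS, FC and PA, PP, PAR, PS, petal_convexity) as CSV aliases.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import ConvexHull
from skimage.measure import regionprops

from .segmentation import BinaryMask, Contour, simplify_contour, trace_contour

__all__ = [
    "ShapeDescriptors",
    "object_area",
    "object_perimeter",
    "best_fit_ellipse",
    "convex_hull_metrics",
    "shape_factors",
    "measure_mask",
    "measure_contour",
    "FLOWER_ALIASES",
    "PETAL_ALIASES",
]

FLOWER_ALIASES = {
    "area_cm2": "FA", "perimeter_cm": "FP", "ellipse_major_cm": "FEM",
    "ellipse_minor_cm": "FEN", "hull_area_cm2": "FHA", "hull_perimeter_cm": "FHP",
    "aspect_ratio": "FAR", "solidity": "FS", "convexity": "FC",
}
PETAL_ALIASES = {
    "area_cm2": "PA", "perimeter_cm": "PP", "ellipse_major_cm": "PEM",
    "ellipse_minor_cm": "PEN", "hull_area_cm2": "PHA", "hull_perimeter_cm": "PHP",
    "aspect_ratio": "PAR", "solidity": "PS", "convexity": "petal_convexity",
}


@dataclass
class ShapeDescriptors:
    area_cm2: float
    perimeter_cm: float
    ellipse_major_cm: float
    ellipse_minor_cm: float
    hull_area_cm2: float
    hull_perimeter_cm: float
    aspect_ratio: float
    solidity: float
    convexity: float
    object_kind: str = "flower"  # or "petal"
    view_label: str = "top"

    def to_dict(self, aliases: bool = True) -> dict:
        """Descriptor dict, optionally keyed by the field mnemonics."""
        names = (FLOWER_ALIASES if self.object_kind == "flower" else PETAL_ALIASES)
        out = {}
        for field_name in (
            "area_cm2", "perimeter_cm", "ellipse_major_cm", "ellipse_minor_cm",
            "hull_area_cm2", "hull_perimeter_cm", "aspect_ratio", "solidity",
            "convexity",
        ):
            key = names[field_name] if aliases else field_name
            out[key] = getattr(self, field_name)
        return out


def object_area(c: Contour) -> float:
    """Shoelace polygon area (cm^2); orientation-independent."""
    a = abs(c.signed_area)
    if a == 0.0:
        raise ValueError("degenerate (collinear) contour has zero area")
    return a


def object_perimeter(c: Contour) -> float:
    """Sum of consecutive vertex distances including the closing edge."""
    return c.perimeter()


def best_fit_ellipse(obj: BinaryMask | Contour) -> tuple[float, float]:
    """Major and minor chord lengths of the moments-equivalent ellipse (cm).

    The ellipse matches the object's second central moments.  Masks use image
    moments of the filled region; analytic contours use exact polygon moments
    (Green's theorem).  Returns (major, minor), major >= minor.
    """
    if isinstance(obj, BinaryMask):
        props = regionprops(obj.pixels.astype(np.uint8))
        if not props:
            raise ValueError("empty mask has no ellipse")
        p = max(props, key=lambda q: q.area)
        major = p.axis_major_length * obj.pixel_size_cm
        minor = p.axis_minor_length * obj.pixel_size_cm
    else:
        major, minor = _polygon_ellipse_axes(obj.points)
    if minor <= 0 or not np.isfinite(major):
        raise ValueError("zero-variance object: ellipse undefined")
    return float(major), float(minor)


def _polygon_ellipse_axes(pts: np.ndarray) -> tuple[float, float]:
    """Axes of the moments-equivalent ellipse of a polygon's interior."""
    x, y = pts[:, 0], pts[:, 1]
    x1, y1 = np.roll(x, -1), np.roll(y, -1)
    cross = x * y1 - x1 * y
    a = 0.5 * cross.sum()
    if a == 0:
        raise ValueError("degenerate polygon")
    cx = ((x + x1) * cross).sum() / (6 * a)
    cy = ((y + y1) * cross).sum() / (6 * a)
    sxx = ((x**2 + x * x1 + x1**2) * cross).sum() / (12 * a) - cx**2
    syy = ((y**2 + y * y1 + y1**2) * cross).sum() / (12 * a) - cy**2
    sxy = ((x * y1 + 2 * x * y + 2 * x1 * y1 + x1 * y) * cross).sum() / (24 * a) - cx * cy
    cov = np.array([[sxx, sxy], [sxy, syy]])
    ev = np.linalg.eigvalsh(cov)
    if ev[0] < 0:
        ev = np.clip(ev, 0, None)
    # ellipse with the same normalized second moments: semi-axis = 2 sqrt(lambda)
    minor, major = 4 * np.sqrt(ev[0]), 4 * np.sqrt(ev[1])
    return float(major), float(minor)


def convex_hull_metrics(c: Contour) -> tuple[float, float]:
    """Area (cm^2) and perimeter (cm) of the convex hull of the vertices."""
    hull = ConvexHull(c.points)
    return float(hull.volume), float(hull.area)  # in 2-D: volume=area, area=perimeter


def shape_factors(
    area_cm2: float,
    perimeter_cm: float,
    ellipse_major_cm: float,
    ellipse_minor_cm: float,
    hull_area_cm2: float,
    hull_perimeter_cm: float,
) -> tuple[float, float, float]:
    """(aspect_ratio, solidity, convexity) from the primary descriptors."""
    if min(ellipse_minor_cm, hull_area_cm2, perimeter_cm) <= 0:
        raise ValueError("shape factors undefined: zero denominator")
    return (
        ellipse_major_cm / ellipse_minor_cm,
        area_cm2 / hull_area_cm2,
        hull_perimeter_cm / perimeter_cm,
    )


def measure_contour(
    c: Contour,
    mask: BinaryMask | None = None,
    object_kind: str = "flower",
    view_label: str = "top",
    smooth_perimeter_px: float = 1.4,
) -> ShapeDescriptors:
    """Full descriptor vector for one object.

    Area and hull metrics come from the contour polygon.  For raster-traced
    contours the perimeter is measured on the Douglas-Peucker-simplified
    polygon (see ``segmentation.simplify_contour``) to remove staircase bias;
    analytic contours are measured as-is.  The ellipse uses mask moments when
    a mask is given, polygon moments otherwise.
    """
    area = object_area(c)
    if c.pixel_size_cm is not None and smooth_perimeter_px > 0:
        perim = object_perimeter(simplify_contour(c, smooth_perimeter_px))
    else:
        perim = object_perimeter(c)
    hull_area, hull_perim = convex_hull_metrics(c)
    major, minor = best_fit_ellipse(mask if mask is not None else c)
    ar, sol, conv = shape_factors(area, perim, major, minor, hull_area, hull_perim)
    if c.pixel_size_cm is not None:
        # raster quantization can push the hull perimeter marginally above the
        # smoothed object perimeter on convex outlines; convexity > 1 is
        # geometrically impossible, so clamp
        conv = min(conv, 1.0)
    return ShapeDescriptors(
        area_cm2=area, perimeter_cm=perim,
        ellipse_major_cm=major, ellipse_minor_cm=minor,
        hull_area_cm2=hull_area, hull_perimeter_cm=hull_perim,
        aspect_ratio=ar, solidity=sol, convexity=conv,
        object_kind=object_kind, view_label=view_label,
    )


def measure_mask(
    mask: BinaryMask,
    object_kind: str = "flower",
    view_label: str = "top",
) -> ShapeDescriptors:
    """Trace the mask boundary and measure all descriptors."""
    c = trace_contour(mask)
    return measure_contour(c, mask=mask, object_kind=object_kind,
                           view_label=view_label)
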