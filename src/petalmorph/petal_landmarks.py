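"""Evenly spaced outline landmarks for petal contours.

A petal outline is reduced to n (default 96) landmarks at equal arc-length
spacing along the margin, anchored at the basal tip of the claw.  The scan
protocol lays petals with the claw pointing downward, so the base tip is the
lowest contour point in image coordinates.  Anchoring translates the base
tip to (0, 0) and flips the y axis so the blade extends toward positive y;
no rotation or scaling is applied — size is deliberately retained so that the
downstream shape model can capture it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .segmentation import Contour

__all__ = [
    "LandmarkSet",
    "find_base_tip",
    "resample_landmarks",
    "anchor_frame",
    "flatten",
    "unflatten",
    "landmarks_from_contour",
]


@dataclass
class LandmarkSet:
    """Ordered (x, y) landmarks in cm; landmark 0 is the claw base tip."""

    points: np.ndarray
    anchored: bool = False

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2 or len(pts) < 3:
            raise ValueError("a landmark set needs at least 3 (x, y) points")
        self.points = pts

    @property
    def n(self) -> int:
        return len(self.points)

    @property
    def base_index(self) -> int:
        return 0

    @property
    def centroid(self) -> np.ndarray:
        return self.points.mean(axis=0)


def flatten(l: LandmarkSet) -> np.ndarray:
    """(x0, y0, x1, y1, ...) coordinate vector of length 2n."""
    return l.points.reshape(-1).copy()


def unflatten(v: np.ndarray, anchored: bool = True) -> LandmarkSet:
    """Inverse of :func:`flatten`."""
    v = np.asarray(v, dtype=float)
    if v.ndim != 1 or v.size % 2:
        raise ValueError("flat landmark vector must have even length")
    return LandmarkSet(v.reshape(-1, 2), anchored=anchored)


def find_base_tip(c: Contour) -> int:
    """Index of the contour vertex at the claw base tip.

    In the image frame y grows downward, so the base tip is the vertex of
    maximal y; ties (flat-bottomed outlines) go to the smallest x.
    """
    pts = c.points
    ymax = pts[:, 1].max()
    at_bottom = np.nonzero(pts[:, 1] == ymax)[0]
    return int(at_bottom[np.argmin(pts[at_bottom, 0])])


def resample_landmarks(c: Contour, base: int | None = None, n: int = 96) -> LandmarkSet:
    """n landmarks at arc-length positions k*L/n from the base vertex.

    Positions follow the contour's stored (positively oriented) direction;
    landmark 0 sits exactly on the base vertex.  The result is independent of
    the starting index of the input vertex list.
    """
    if n < 3:
        raise ValueError("need at least 3 landmarks")
    if base is None:
        base = find_base_tip(c)
    pts = np.roll(c.points, -base, axis=0)
    closed = np.vstack([pts, pts[:1]])
    seg = np.hypot(*np.diff(closed, axis=0).T)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    total = s[-1]
    if total <= 0:
        raise ValueError("zero-length contour")
    targets = np.arange(n) * total / n
    x = np.interp(targets, s, closed[:, 0])
    y = np.interp(targets, s, closed[:, 1])
    return LandmarkSet(np.column_stack([x, y]), anchored=False)


def anchor_frame(l: LandmarkSet) -> LandmarkSet:
    """Anchor landmarks: base tip at (0, 0), blade toward positive y.

    Translation only (no rotation, no scaling).  The y axis is flipped when
    the blade currently extends toward negative y, which makes the operation
    idempotent.  The traversal direction is disambiguated so that the first
    step from the base goes toward non-negative x.
    """
    pts = l.points - l.points[0]
    if pts[:, 1].mean() < 0:
        pts = pts * np.array([1.0, -1.0])
    if pts[1, 0] < 0 and abs(pts[1, 0]) > 1e-12:
        pts = np.vstack([pts[:1], pts[1:][::-1]])
    return LandmarkSet(pts, anchored=True)


def landmarks_from_contour(c: Contour, n: int = 96,
                           base: int | None = None) -> LandmarkSet:
    """Convenience chain: find base tip, resample, anchor."""
    return anchor_frame(resample_landmarks(c, base=base, n=n))
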