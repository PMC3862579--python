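"""Ground-truthed synthetic petals, flowers and clonal populations.

No reference image collection is distributed with this package, so every
raster-pipeline and quantitative-genetics routine is validated against
synthetic data whose true geometry and true genetic parameters are known by
construction:

* ``make_petal_polygon`` builds a petal as a pointed claw joined to a
  parametric blade (obovate / reniform / fan profiles), with optional
  sinusoidal marginal serration on the distal blade margin and an optional
  asymmetric shear.  The ground-truth record carries exact polygon
  descriptors computed with shapely and closed-form polygon moments — a code
  path independent of the raster measurement pipeline.
* ``rasterize`` fills a polygon into the red channel of an RGB frame without
  antialiasing (pixel centers strictly inside the polygon) and returns the
  identical boolean mask as ground truth.
* ``make_flower_rosette`` unions rotated petals into a top-view flower, with
  seeded angular/radial jitter to emulate irregular petal arrangement.
* ``simulate_clonal_population`` draws trait tables from the clonal-design
  model value(g, r, e) = mu + G_g + shift(e) * delta_g + eps with
  multivariate-normal genotype effects, recording true H^2, r_G and
  reaction-norm slopes.

All generators are deterministic given (spec, seed).  Polygons are emitted
in the image frame (y increases downward, claw tip at maximal y), matching
what the segmentation pipeline produces.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import Polygon as ShPolygon
from shapely.ops import unary_union

from .segmentation import BinaryMask, RasterImage, calibrate

__all__ = [
    "PetalSpec",
    "PopulationSpec",
    "GroundTruth",
    "make_petal_polygon",
    "make_flower_rosette",
    "rasterize",
    "polygon_oracle",
    "simulate_clonal_population",
]

BLADE_PROFILES = {
    # (a, b) exponents of the normalized beta-like half-width profile
    # v^a (1-v)^b: peak at a/(a+b) along the blade axis
    "obovate": (1.3, 0.7),   # widest above the middle, narrow base
    "reniform": (1.5, 0.5),  # wide, blunt, kidney-like top
    "fan": (1.9, 0.35),      # widening almost to the top
}


@dataclass
class PetalSpec:
    """Parameters of a synthetic petal (lengths in cm)."""

    blade_width: float = 3.2
    blade_length: float = 3.0
    claw_width: float = 0.9
    claw_length: float = 2.2
    serration_amplitude: float = 0.0
    serration_count: int = 0
    asymmetry_skew: float = 0.0
    blade_shape: str = "obovate"

    def __post_init__(self) -> None:
        if min(self.blade_width, self.blade_length,
               self.claw_width, self.claw_length) <= 0:
            raise ValueError("all petal lengths must be positive")
        if self.serration_count < 0 or self.serration_amplitude < 0:
            raise ValueError("serration parameters must be nonnegative")
        if self.blade_shape not in BLADE_PROFILES:
            raise ValueError(f"unknown blade shape {self.blade_shape!r}")


@dataclass
class GroundTruth:
    """Exact polygon descriptors + the claw base tip, all in image-frame cm."""

    polygon: np.ndarray
    area: float
    perimeter: float
    hull_area: float
    hull_perimeter: float
    solidity: float
    convexity: float
    base_tip: tuple[float, float]
    ellipse_major: float | None = None
    ellipse_minor: float | None = None


def polygon_oracle(pts: np.ndarray, base_tip: tuple[float, float],
                   with_ellipse: bool = True) -> GroundTruth:
    """Exact descriptors of a polygon via shapely + polygon moments."""
    poly = ShPolygon(pts)
    hull = poly.convex_hull
    if with_ellipse:
        from .morphometry import _polygon_ellipse_axes
        major, minor = _polygon_ellipse_axes(np.asarray(pts, dtype=float))
    else:
        major = minor = None
    return GroundTruth(
        polygon=np.asarray(pts, dtype=float),
        area=poly.area,
        perimeter=poly.exterior.length,
        hull_area=hull.area,
        hull_perimeter=hull.exterior.length,
        solidity=poly.area / hull.area,
        convexity=hull.exterior.length / poly.exterior.length,
        base_tip=tuple(base_tip),
        ellipse_major=major,
        ellipse_minor=minor,
    )


def _blade_halfwidth(v: np.ndarray, spec: PetalSpec) -> np.ndarray:
    a, b = BLADE_PROFILES[spec.blade_shape]
    peak = (a / (a + b)) ** a * (b / (a + b)) ** b
    return 0.5 * spec.blade_width * (v**a * (1 - v) ** b) / peak


def _petal_points_yup(spec: PetalSpec, n_blade: int = 1500) -> np.ndarray:
    """Petal boundary in a y-up frame, claw base tip at the origin."""
    cl, cw, bl = spec.claw_length, spec.claw_width, spec.blade_length
    # claw: pointed tip widening to the full claw width; overlaps the blade
    claw = ShPolygon([
        (0.0, 0.0),
        (0.18 * cw, 0.06 * cl),
        (0.5 * cw, cl),
        (0.5 * cw, cl + 0.25 * bl),
        (-0.5 * cw, cl + 0.25 * bl),
        (-0.5 * cw, cl),
        (-0.18 * cw, 0.06 * cl),
    ])
    # blade: beta-profile half-width along the axis, from y0 to y0 + bl
    y0 = 0.92 * cl
    v = np.linspace(0.0, 1.0, n_blade // 2)[1:-1]
    w = _blade_halfwidth(v, spec)
    y = y0 + v * bl
    right = np.column_stack([w, y])
    left = np.column_stack([-w[::-1], y[::-1]])
    blade_pts = np.vstack([[0.0, y0], right, [0.0, y0 + bl], left])
    blade = ShPolygon(blade_pts)
    union = unary_union([claw, blade])
    if union.geom_type != "Polygon":
        raise ValueError("petal parameters produce a disconnected outline")
    pts = np.asarray(union.exterior.coords)[:-1]

    if spec.serration_count > 0 and spec.serration_amplitude > 0:
        pts = _serrate(pts, spec, y0)
    if spec.asymmetry_skew != 0.0:
        shear = spec.asymmetry_skew * np.clip(pts[:, 1] - y0, 0, None) / bl
        pts = pts + np.column_stack([shear * spec.blade_width, np.zeros(len(pts))])
    if not ShPolygon(pts).is_valid:
        raise ValueError("self-intersecting petal outline; reduce serration "
                         "amplitude or asymmetry skew")
    return pts


def _serrate(pts: np.ndarray, spec: PetalSpec, y0: float) -> np.ndarray:
    """Radial sinusoidal teeth on the distal blade margin.

    Displacement is radial from the blade center, which cannot introduce
    self-intersections as long as the radius stays positive; a smoothstep
    taper restricts the teeth to the distal half of the blade.
    """
    bl = spec.blade_length
    center = np.array([0.0, y0 + 0.5 * bl])
    rel = pts - center
    r = np.hypot(rel[:, 0], rel[:, 1])
    phi = np.arctan2(rel[:, 1], rel[:, 0])
    t = np.clip((pts[:, 1] - (y0 + 0.45 * bl)) / (0.2 * bl), 0.0, 1.0)
    taper = t * t * (3 - 2 * t)
    # the distal margin spans roughly |phi - pi/2| < 1.25 rad; one full tooth
    # period per (window / serration_count)
    window = 2.5
    phase = spec.serration_count * 2 * np.pi * (phi - np.pi / 2) / window
    offset = 0.5 * spec.serration_amplitude * np.cos(phase) * taper
    r_new = np.clip(r + offset, 1e-6, None)
    out = center + np.column_stack([r_new * np.cos(phi), r_new * np.sin(phi)])
    return out


def _to_image_frame(pts: np.ndarray, margin: float = 0.1) -> tuple[np.ndarray, np.ndarray]:
    """Flip a y-up polygon into image coordinates (y down, all coords > 0)."""
    x0, y1 = pts[:, 0].min(), pts[:, 1].max()
    out = np.column_stack([pts[:, 0] - x0 + margin, (y1 - pts[:, 1]) + margin])
    return out, np.array([x0 - margin, y1 + margin])


def make_petal_polygon(spec: PetalSpec) -> tuple[np.ndarray, GroundTruth]:
    """Petal polygon (image-frame cm) and its exact ground-truth record."""
    pts_up = _petal_points_yup(spec)
    pts, _ = _to_image_frame(pts_up)
    # the claw tip was at the y-up origin: in the image frame it is the
    # unique point of maximal y
    tip_idx = int(np.argmax(pts[:, 1]))
    truth = polygon_oracle(pts, base_tip=tuple(pts[tip_idx]))
    return pts, truth


def make_flower_rosette(
    petal: PetalSpec,
    petal_count: int = 8,
    jitter: float = 0.0,
    seed: int | np.random.Generator = 0,
    sharpness_cm: float = 0.03,
) -> tuple[np.ndarray, GroundTruth]:
    """Top-view flower: union of rotated petals with seeded jitter.

    ``jitter`` is the SD of the angular perturbation (radians) and of the
    radial offset as a fraction of the claw length.  Petals are shifted
    toward the center so their claws overlap into a solid disc.  The union
    is regularized by a morphological closing of radius ``sharpness_cm``:
    near-tangent petal edges otherwise leave arbitrarily thin crevices that
    no photograph of a real corolla would show (and no raster could
    resolve); the ground-truth record describes the regularized polygon
    exactly.
    """
    if petal_count < 3:
        raise ValueError("a rosette needs at least 3 petals")
    rng = np.random.default_rng(seed) if isinstance(seed, (int, np.integer)) else seed
    base = _petal_points_yup(petal)
    pull = 0.45 * petal.claw_length
    polys = []
    for k in range(petal_count):
        ang = 2 * np.pi * k / petal_count + jitter * rng.normal()
        radial = -pull * (1 + jitter * rng.normal())
        shifted = base + np.array([0.0, radial])
        c, s = np.cos(ang), np.sin(ang)
        rot = shifted @ np.array([[c, s], [-s, c]])
        polys.append(ShPolygon(rot))
    union = unary_union(polys)
    if sharpness_cm > 0:
        union = union.buffer(sharpness_cm, quad_segs=16).buffer(
            -sharpness_cm, quad_segs=16)
    if union.geom_type != "Polygon":
        raise ValueError("rosette petals do not overlap into a single flower")
    pts_up = np.asarray(ShPolygon(union.exterior).exterior.coords)[:-1]
    pts, _ = _to_image_frame(pts_up)
    tip_idx = int(np.argmax(pts[:, 1]))
    truth = polygon_oracle(pts, base_tip=tuple(pts[tip_idx]))
    return pts, truth


def rasterize(
    polygon: np.ndarray,
    dpi: float = 800.0,
    red_level: int = 200,
    background_level: int = 10,
    frame_shape: tuple[int, int] | None = None,
    view_label: str = "petal_scan",
) -> tuple[RasterImage, BinaryMask]:
    """Antialiasing-free raster of a polygon into the red channel.

    A pixel is foreground iff its center lies strictly inside the polygon.
    The returned mask is that same fill — the ground truth the segmentation
    round-trip is compared against.
    """
    s = calibrate(dpi)
    poly = np.asarray(polygon, dtype=float)
    if frame_shape is None:
        h = int(np.ceil(poly[:, 1].max() / s)) + 2
        w = int(np.ceil(poly[:, 0].max() / s)) + 2
    else:
        h, w = frame_shape
        if poly[:, 1].max() > h * s or poly[:, 0].max() > w * s or poly.min() < 0:
            raise ValueError("polygon exceeds the raster frame")
    shp = ShPolygon(poly)
    shapely.prepare(shp)
    cols, rows = np.meshgrid(np.arange(w), np.arange(h))
    xs = (cols.ravel() + 0.5) * s
    ys = (rows.ravel() + 0.5) * s
    inside = shapely.contains_xy(shp, xs, ys).reshape(h, w)
    img = np.full((h, w, 3), background_level, dtype=np.uint8)
    img[:, :, 0][inside] = red_level
    return (
        RasterImage(img, dpi=dpi, view_label=view_label),
        BinaryMask(inside, pixel_size_cm=s),
    )


def make_latent_factor_petals(
    n: int = 200,
    factor_sds: tuple[float, ...] = (1.0, 0.7, 0.45, 0.3),
    noise_sd: float = 0.01,
    n_landmarks: int = 96,
    seed: int | np.random.Generator = 0,
    base: PetalSpec | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Anchored landmark vectors driven by independent latent shape factors.

    The factor directions are the (Gram-Schmidt orthonormalized) sensitivities
    of the anchored landmark vector to blade width, blade length, claw length
    and asymmetric shear around a base petal, so each factor is a real,
    interpretable mode of petal-shape variation; samples are
    ``mean + sum_k t_k sd_k q_k + noise`` with t ~ N(0, 1) i.i.d.  Returns
    ``(X, factors)``: the (n, 2*n_landmarks) coordinate matrix and the
    (n, k) latent factor draws — the ground truth a fitted PCA model should
    recover when the factor SDs are distinct and the noise is small.
    """
    from .petal_landmarks import flatten, landmarks_from_contour
    from .segmentation import Contour

    rng = np.random.default_rng(seed) if isinstance(seed, (int, np.integer)) else seed
    base = base or PetalSpec()

    def land(sp: PetalSpec) -> np.ndarray:
        poly, _ = make_petal_polygon(sp)
        return flatten(landmarks_from_contour(Contour(poly), n=n_landmarks))

    mean = land(base)
    eps = 0.05
    tweaks = [
        PetalSpec(base.blade_width + eps, base.blade_length, base.claw_width,
                  base.claw_length, blade_shape=base.blade_shape),
        PetalSpec(base.blade_width, base.blade_length + eps, base.claw_width,
                  base.claw_length, blade_shape=base.blade_shape),
        PetalSpec(base.blade_width, base.blade_length, base.claw_width,
                  base.claw_length + eps, blade_shape=base.blade_shape),
        PetalSpec(base.blade_width, base.blade_length, base.claw_width,
                  base.claw_length, asymmetry_skew=eps,
                  blade_shape=base.blade_shape),
    ][: len(factor_sds)]
    dirs = np.vstack([(land(sp) - mean) / eps for sp in tweaks])
    q, _ = np.linalg.qr(dirs.T)  # orthonormal factor directions, columns
    factors = rng.normal(size=(n, len(factor_sds)))
    X = (mean + (factors * np.asarray(factor_sds)) @ q.T
         + noise_sd * rng.normal(size=(n, mean.size)))
    return X, factors


@dataclass
class PopulationSpec:
    """Design of a simulated clonal population.

    Defaults emulate a standard-carnation-scale flower experiment: 55
    genotypes, 5 clonal replicates, area (cm^2) and convexity traits with
    genetic/environmental SDs chosen to give H^2 of about 0.75 and 0.83 and
    genetic CVs near 19% and 17%.
    """

    n_genotypes: int = 55
    n_replicates: int = 5
    traits: tuple[str, ...] = ("area", "convexity")
    mu: tuple[float, ...] = (33.0, 0.80)
    sd_g: tuple[float, ...] = (6.2, 0.137)
    sd_e: tuple[float, ...] = (3.6, 0.062)
    corr: np.ndarray | None = None  # genetic correlation matrix, default identity
    env_shift: dict[str, float] | None = None  # e.g. {"autumn": 0.0, "winter": 1.0}
    gxe_sd: float = 0.3  # SD of per-genotype environmental sensitivity around 1
    population: str = "entire"

    def __post_init__(self) -> None:
        if self.n_genotypes < 2 or self.n_replicates < 1:
            raise ValueError("need >= 2 genotypes and >= 1 replicate")
        k = len(self.traits)
        if not (len(self.mu) == len(self.sd_g) == len(self.sd_e) == k):
            raise ValueError("mu, sd_g, sd_e must match the trait list")
        if self.corr is None:
            self.corr = np.eye(k)
        self.corr = np.asarray(self.corr, dtype=float)
        if self.corr.shape != (k, k) or not np.allclose(self.corr, self.corr.T):
            raise ValueError("genetic correlation matrix must be symmetric k x k")
        if np.linalg.eigvalsh(self.corr).min() < -1e-10:
            raise ValueError("genetic correlation matrix is not positive semidefinite")


_ENV_DATES = {"autumn": "2012-11-15", "winter": "2013-01-20"}


def simulate_clonal_population(
    spec: PopulationSpec,
    seed: int | np.random.Generator = 0,
) -> tuple[pd.DataFrame, dict]:
    """Draw a long-form trait table from the clonal-design model.

    value(g, r, e) = mu + G_g + shift(e) * delta_g + eps_{g,r}, with
    G ~ MVN(0, diag(sd_g) corr diag(sd_g)) shared by all replicates of a
    genotype and eps ~ Normal(0, sd_e) independent.  Returns the table and a
    truth record with the realized generator parameters: per-trait true
    H^2 = sd_g^2 / (sd_g^2 + sd_e^2), the true genetic correlation matrix,
    and per-genotype reaction-norm slopes when environments are simulated.
    """
    rng = np.random.default_rng(seed) if isinstance(seed, (int, np.integer)) else seed
    k = len(spec.traits)
    d = np.diag(spec.sd_g)
    cov = d @ spec.corr @ d
    G = rng.multivariate_normal(np.zeros(k), cov, size=spec.n_genotypes,
                                method="svd")
    genotypes = [f"g{i:03d}" for i in range(spec.n_genotypes)]
    if spec.env_shift:
        envs = sorted(spec.env_shift)
        delta = 1.0 + spec.gxe_sd * rng.normal(size=spec.n_genotypes)
    else:
        envs, delta = [None], np.zeros(spec.n_genotypes)

    rows = []
    for gi, g in enumerate(genotypes):
        for r in range(spec.n_replicates):
            env = envs[r % len(envs)] if envs[0] is not None else None
            shift = spec.env_shift[env] if env is not None else 0.0
            eps = rng.normal(size=k) * np.asarray(spec.sd_e)
            vals = np.asarray(spec.mu) + G[gi] + shift * delta[gi] + eps
            for t, vv in zip(spec.traits, vals):
                rows.append({
                    "genotype": g, "replicate": r,
                    "environment": env if env is not None else "single",
                    "collection_date": _ENV_DATES.get(env, "2012-12-01"),
                    "population": spec.population,
                    "trait": t, "value": vv,
                })
    table = pd.DataFrame(rows)
    sg = np.asarray(spec.sd_g)
    se = np.asarray(spec.sd_e)
    truth = {
        "h2": {t: float(sg[i] ** 2 / (sg[i] ** 2 + se[i] ** 2))
               for i, t in enumerate(spec.traits)},
        "r_g": spec.corr.copy(),
        "genotype_effects": {g: G[i] for i, g in enumerate(genotypes)},
    }
    if spec.env_shift:
        span = max(spec.env_shift.values()) - min(spec.env_shift.values())
        truth["slopes"] = {g: float(span * delta[i]) for i, g in enumerate(genotypes)}
    return table, truth
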