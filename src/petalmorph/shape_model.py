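"""Principal-component model of petal outline variation.

Landmark sets (n landmarks -> 2n-vector) are decomposed by PCA on the sample
covariance of the raw anchored coordinates (covariance PCA in cm, not
correlation PCA: size is part of shape here, and the leading components are
expected to be size-sensitive).  The model supports reconstruction of shapes
at +/- k standard deviations along a component — the standard way of
visualizing what each component does — projection of new petals into score
space, and per-cultivar score summaries (centroid and 1-SD axis-aligned
ellipse in a chosen component plane).

Component signs are arbitrary in any eigendecomposition; for determinism
each component is oriented so that its largest-magnitude loading is
positive.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .petal_landmarks import LandmarkSet, flatten, unflatten

__all__ = [
    "ShapeModel",
    "fit_shape_model",
    "reconstruct_at_sd",
    "project",
    "cultivar_summary",
]


@dataclass
class ShapeModel:
    """PCA decomposition of flattened landmark vectors.

    mean_shape : (2n,) mean coordinate vector
    components : (k, 2n) orthonormal rows, ordered by decreasing variance
    sdevs : (k,) standard deviations of the training scores per component
    variance_fraction : (k,) eigenvalue / total variance, non-increasing
    """

    mean_shape: np.ndarray
    components: np.ndarray
    sdevs: np.ndarray
    variance_fraction: np.ndarray

    @property
    def n_components(self) -> int:
        return len(self.components)

    @property
    def n_landmarks(self) -> int:
        return self.mean_shape.size // 2

    def cumulative_variance(self, k: int | None = None) -> float:
        """Cumulative variance fraction of the first k components."""
        k = self.n_components if k is None else k
        return float(self.variance_fraction[:k].sum())


def _as_matrix(landmarks: Iterable[LandmarkSet] | np.ndarray) -> np.ndarray:
    if isinstance(landmarks, np.ndarray):
        return np.asarray(landmarks, dtype=float)
    rows = [flatten(l) for l in landmarks]
    sizes = {r.size for r in rows}
    if len(sizes) > 1:
        raise ValueError("all landmark sets must have the same landmark count")
    return np.vstack(rows)


def fit_shape_model(
    landmarks: Iterable[LandmarkSet] | np.ndarray,
    n_components: int | None = None,
) -> ShapeModel:
    """Fit the PCA shape model to a training set of landmark vectors.

    Eigendecomposition of the sample covariance (ddof=1).  All components
    with nonzero variance are kept unless ``n_components`` truncates them.
    """
    X = _as_matrix(landmarks)
    m, p = X.shape
    if m < 2:
        raise ValueError("need at least 2 petals to fit a shape model")
    mean = X.mean(axis=0)
    Xc = X - mean
    cov = Xc.T @ Xc / (m - 1)
    total = np.trace(cov)
    if total <= 0:
        raise ValueError("zero variance: all petals identical")
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    comps = evecs[:, order].T
    # deterministic sign: largest-|loading| entry positive
    for i in range(len(comps)):
        j = np.argmax(np.abs(comps[i]))
        if comps[i, j] < 0:
            comps[i] = -comps[i]
    k = min(m - 1, p) if n_components is None else n_components
    return ShapeModel(
        mean_shape=mean,
        components=comps[:k],
        sdevs=np.sqrt(evals[:k]),
        variance_fraction=evals[:k] / total,
    )


def reconstruct_at_sd(m: ShapeModel, component: int, k: float) -> LandmarkSet:
    """Shape at ``k`` standard deviations from the mean along one component."""
    if not 0 <= component < m.n_components:
        raise IndexError(f"component {component} out of range")
    if not np.isfinite(k):
        raise ValueError("k must be finite")
    v = m.mean_shape + k * m.sdevs[component] * m.components[component]
    return unflatten(v)


def project(
    m: ShapeModel,
    landmarks: LandmarkSet | Iterable[LandmarkSet] | np.ndarray,
    sd_units: bool = False,
) -> np.ndarray:
    """Component scores of one or more landmark sets.

    Returns a (k,) vector for a single set, (m, k) otherwise.  With
    ``sd_units`` scores are divided by the per-component training SD.
    """
    single = isinstance(landmarks, LandmarkSet)
    X = flatten(landmarks)[None, :] if single else _as_matrix(landmarks)
    if X.shape[1] != m.mean_shape.size:
        raise ValueError("landmark count does not match the model")
    scores = (X - m.mean_shape) @ m.components.T
    if sd_units:
        with np.errstate(divide="ignore", invalid="ignore"):
            scores = np.where(m.sdevs > 0, scores / m.sdevs, 0.0)
    return scores[0] if single else scores


def cultivar_summary(
    scores: np.ndarray,
    cultivars: Sequence[str],
    plane: tuple[int, int] = (0, 1),
) -> pd.DataFrame:
    """Per-cultivar centroid and 1-SD axis-aligned ellipse in a score plane.

    Returns a DataFrame indexed by cultivar with columns mean_x, mean_y,
    sd_x, sd_y, n, singleton.  Singleton cultivars get zero-radius ellipses
    and are flagged.
    """
    scores = np.asarray(scores, dtype=float)
    i, j = plane
    df = pd.DataFrame({
        "cultivar": list(cultivars),
        "x": scores[:, i],
        "y": scores[:, j],
    })
    g = df.groupby("cultivar", sort=True)
    out = pd.DataFrame({
        "mean_x": g["x"].mean(),
        "mean_y": g["y"].mean(),
        "sd_x": g["x"].std(ddof=1),
        "sd_y": g["y"].std(ddof=1),
        "n": g.size(),
    })
    out["singleton"] = out["n"] < 2
    out[["sd_x", "sd_y"]] = out[["sd_x", "sd_y"]].fillna(0.0)
    return out
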