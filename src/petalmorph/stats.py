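"""Descriptive statistics, distribution fits and group comparisons.

Trait distributions are compared against normal, log-normal and logistic
families by maximum likelihood, ranked by the one-sample Kolmogorov-Smirnov
statistic.  Because the parameters are estimated from the same sample, the
KS p-values are approximate (Lilliefors-type bias) and labeled as such; the
*ranking* by KS statistic — which family tracks the data most closely — is
the quantity of interest.

Group comparisons follow the usual two-track protocol: parametric (t-test
for two groups, ANOVA F with a protected Fisher's LSD follow-up for more)
or non-parametric (Mann-Whitney U, Kruskal-Wallis), with medians reported in
non-parametric mode.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "FitReport",
    "GroupComparison",
    "fit_distributions",
    "compare_groups",
    "fishers_lsd",
    "pearson_r",
]

FAMILIES = ("normal", "log-normal", "logistic")
_DISTS = {"normal": sps.norm, "log-normal": sps.lognorm, "logistic": sps.logistic}


@dataclass
class FitReport:
    family: str
    params: tuple
    ks_stat: float
    ks_pvalue: float  # approximate: parameters estimated from the sample
    best: bool = False
    note: str = ""


def fit_distributions(values, families=FAMILIES) -> list[FitReport]:
    """Fit each candidate family by ML and rank by KS statistic.

    The report with the smallest KS statistic is flagged ``best``.
    Log-normal is skipped (with a note) when any value is non-positive.
    """
    x = np.asarray(values, dtype=float)
    x = x[np.isfinite(x)]
    if len(x) < 8:
        raise ValueError("need at least 8 finite values to fit distributions")
    if np.ptp(x) == 0:
        raise ValueError("degenerate fit: constant sample")
    reports: list[FitReport] = []
    for fam in families:
        dist = _DISTS[fam]
        if fam == "log-normal":
            if (x <= 0).any():
                reports.append(FitReport(fam, (), np.nan, np.nan,
                                         note="skipped: non-positive values"))
                continue
            params = dist.fit(x, floc=0)
        else:
            params = dist.fit(x)
        d, p = sps.kstest(x, dist.cdf, args=params)
        reports.append(FitReport(fam, tuple(params), float(d), float(p)))
    fitted = [r for r in reports if np.isfinite(r.ks_stat)]
    if fitted:
        min(fitted, key=lambda r: r.ks_stat).best = True
    return reports


@dataclass
class GroupComparison:
    method: str
    statistic: float
    pvalue: float
    centers: dict  # group -> mean (parametric) or median (non-parametric)
    pairwise: pd.DataFrame | None = field(default=None, repr=False)


def compare_groups(groups: dict, parametric: bool = True,
                   alpha: float = 0.05) -> GroupComparison:
    """Compare ≥2 groups of values.

    Two groups: t-test (parametric) or Mann-Whitney U.  More: ANOVA F with
    a protected Fisher's LSD follow-up (only when the omnibus F is
    significant at alpha), or Kruskal-Wallis.
    """
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    arrays = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    if parametric and any(len(v) < 2 for v in arrays.values()):
        raise ValueError("parametric comparison needs >= 2 values per group")
    vals = list(arrays.values())
    if parametric:
        centers = {k: float(v.mean()) for k, v in arrays.items()}
        if len(vals) == 2:
            if all(np.ptp(v) == 0 for v in vals) and vals[0].mean() == vals[1].mean():
                return GroupComparison("t-test", 0.0, 1.0, centers)
            t, p = sps.ttest_ind(*vals)
            return GroupComparison("t-test", float(t), float(p), centers)
        f, p = sps.f_oneway(*vals)
        if not np.isfinite(f):  # all groups identical
            f, p = 0.0, 1.0
        pw = fishers_lsd(arrays, alpha=alpha) if p < alpha else None
        return GroupComparison("anova-F", float(f), float(p), centers, pairwise=pw)
    centers = {k: float(np.median(v)) for k, v in arrays.items()}
    if len(vals) == 2:
        u, p = sps.mannwhitneyu(*vals, alternative="two-sided")
        return GroupComparison("mann-whitney-U", float(u), float(p), centers)
    h, p = sps.kruskal(*vals)
    return GroupComparison("kruskal-wallis", float(h), float(p), centers)


def fishers_lsd(groups: dict, alpha: float = 0.05) -> pd.DataFrame:
    """All pairwise Fisher LSD t-tests using the pooled within-group MSE."""
    names = list(groups)
    arrays = [np.asarray(groups[k], dtype=float) for k in names]
    n_tot = sum(len(a) for a in arrays)
    k = len(arrays)
    mse = sum(((a - a.mean()) ** 2).sum() for a in arrays) / (n_tot - k)
    rows = []
    for i in range(k):
        for j in range(i + 1, k):
            a, b = arrays[i], arrays[j]
            se = np.sqrt(mse * (1 / len(a) + 1 / len(b)))
            t = (a.mean() - b.mean()) / se if se > 0 else 0.0
            p = 2 * sps.t.sf(abs(t), df=n_tot - k)
            rows.append({"group1": names[i], "group2": names[j],
                         "diff": a.mean() - b.mean(), "t": t, "p": p,
                         "significant": p < alpha})
    return pd.DataFrame(rows)


def pearson_r(x, y) -> tuple[float, float]:
    """Pearson product-moment correlation and its two-sided p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need equal-length vectors with >= 3 points")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance: correlation undefined")
    r, p = sps.pearsonr(x, y)
    return float(r), float(p)
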