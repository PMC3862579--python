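"""Quantitative genetics on clonal trait tables.

In clonally propagated crops every plant of a cultivar is genetically
identical, so phenotypic variation *within* a genotype is environmental and
variation *among* genotype means carries the genetic signal.  A one-way
ANOVA across genotypes then yields broad-sense heritability:

    MS_W = V_E            (within-genotype mean square)
    MS_A = V_E + n * V_G  (among-genotype mean square)
    V_G  = (MS_A - MS_W) / n_bar,   H^2 = V_G / (V_G + V_E)

where n_bar is the average number of samples per genotype (used as a real
number; designs here are rarely balanced).  Negative V_G estimates are
clamped to zero and flagged, the standard practice for method-of-moments
variance components.

Genetic correlations between two traits use the cross-product analogue of
the same decomposition: cov_G = (MCP_A - MCP_W) / n_bar with MCP the
among/within mean cross-products, and r_G = cov_G / sqrt(V_G1 * V_G2).
A simpler estimate — the plain covariance/correlation of genotype means —
is available via ``method="genotype_means"``.

Trait tables are long-form DataFrames with columns
``genotype, replicate, environment, trait, value`` (plus optional
``population`` and ``collection_date``).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "VarianceComponents",
    "HeritabilityEstimate",
    "GeneticCorrelation",
    "anova_components",
    "broad_sense_heritability",
    "estimate_heritability",
    "genetic_correlation",
    "standardize_traits",
    "reaction_norm",
    "heritability_table",
]

REQUIRED_COLUMNS = ("genotype", "trait", "value")


@dataclass
class VarianceComponents:
    trait: str
    ms_among: float
    ms_within: float
    n_bar: float
    mean: float
    n_genotypes: int
    n_total: int
    clamped: bool = False

    @property
    def v_e(self) -> float:
        return self.ms_within

    @property
    def v_g(self) -> float:
        return max(0.0, (self.ms_among - self.ms_within) / self.n_bar)


@dataclass
class HeritabilityEstimate:
    trait: str
    h2: float
    cv_g: float | None
    v_g: float
    v_e: float
    degenerate: bool = False


@dataclass
class GeneticCorrelation:
    trait1: str
    trait2: str
    cov_g: float
    r_g: float | None
    v_g1: float
    v_g2: float


def _trait_values(t: pd.DataFrame, trait: str) -> pd.DataFrame:
    missing = [c for c in REQUIRED_COLUMNS if c not in t.columns]
    if missing:
        raise ValueError(f"trait table lacks columns {missing}")
    sub = t[t["trait"] == trait]
    if sub.empty:
        raise ValueError(f"no observations for trait {trait!r}")
    if not np.isfinite(sub["value"]).all():
        raise ValueError(f"non-finite values for trait {trait!r}")
    return sub


def anova_components(t: pd.DataFrame, trait: str) -> VarianceComponents:
    """One-way ANOVA variance components for one trait across genotypes."""
    sub = _trait_values(t, trait)
    groups = sub.groupby("genotype")["value"]
    counts = groups.count()
    n_genotypes = len(counts)
    n_total = int(counts.sum())
    if n_genotypes < 2:
        raise ValueError("variance components need at least 2 genotypes")
    if n_total == n_genotypes:
        raise ValueError("within-genotype mean square undefined: "
                         "all genotypes have a single observation")
    grand = sub["value"].mean()
    means = groups.mean()
    ss_among = float((counts * (means - grand) ** 2).sum())
    ss_within = float(((sub["value"] - means.reindex(sub["genotype"]).to_numpy()) ** 2).sum())
    ms_among = ss_among / (n_genotypes - 1)
    ms_within = ss_within / (n_total - n_genotypes)
    n_bar = n_total / n_genotypes
    clamped = (ms_among - ms_within) < 0
    return VarianceComponents(
        trait=trait, ms_among=ms_among, ms_within=ms_within, n_bar=n_bar,
        mean=float(grand), n_genotypes=n_genotypes, n_total=n_total,
        clamped=clamped,
    )


def broad_sense_heritability(v: VarianceComponents) -> HeritabilityEstimate:
    """H^2 = V_G / (V_G + V_E) and CV_G = 100 sqrt(V_G) / mean."""
    vg, ve = v.v_g, v.v_e
    if vg + ve == 0:
        return HeritabilityEstimate(v.trait, 0.0, 0.0, 0.0, 0.0, degenerate=True)
    h2 = vg / (vg + ve)
    cv_g = 100.0 * np.sqrt(vg) / v.mean if v.mean != 0 else None
    return HeritabilityEstimate(v.trait, float(h2), cv_g, vg, ve)


def estimate_heritability(t: pd.DataFrame, trait: str) -> HeritabilityEstimate:
    """Convenience chain: ANOVA components then heritability."""
    return broad_sense_heritability(anova_components(t, trait))


def genetic_correlation(
    t: pd.DataFrame,
    trait1: str,
    trait2: str,
    method: str = "components",
) -> GeneticCorrelation:
    """Genetic correlation between two traits measured on the same samples.

    ``components`` (default): among-genotype covariance component from mean
    cross-products, symmetric with the variance-component definition.
    ``genotype_means``: plain covariance of genotype means.
    """
    keys = [c for c in ("genotype", "replicate", "environment") if c in t.columns]
    w1 = _trait_values(t, trait1).set_index(keys)["value"]
    w2 = _trait_values(t, trait2).set_index(keys)["value"]
    pair = pd.DataFrame({"x": w1, "y": w2}).dropna().reset_index()
    if pair.empty:
        raise ValueError("traits share no samples")

    def components_of(col: str) -> VarianceComponents:
        sub = pair[["genotype", col]].rename(columns={col: "value"})
        sub = sub.assign(trait="t")
        return anova_components(sub, "t")

    v1, v2 = components_of("x"), components_of("y")
    g = pair.groupby("genotype")
    counts = g.size()
    n_gen = len(counts)
    n_tot = int(counts.sum())
    n_bar = n_tot / n_gen
    mx = g["x"].mean()
    my = g["y"].mean()
    if method == "components":
        scp_among = float((counts * (mx - pair["x"].mean()) * (my - pair["y"].mean())).sum())
        dev_x = pair["x"] - mx.reindex(pair["genotype"]).to_numpy()
        dev_y = pair["y"] - my.reindex(pair["genotype"]).to_numpy()
        scp_within = float((dev_x * dev_y).sum())
        mcp_a = scp_among / (n_gen - 1)
        mcp_w = scp_within / (n_tot - n_gen)
        cov_g = (mcp_a - mcp_w) / n_bar
    elif method == "genotype_means":
        cov_g = float(np.cov(mx, my, ddof=1)[0, 1])
    else:
        raise ValueError(f"unknown method {method!r}")
    if v1.v_g <= 0 or v2.v_g <= 0:
        return GeneticCorrelation(trait1, trait2, cov_g, None, v1.v_g, v2.v_g)
    r = float(np.clip(cov_g / np.sqrt(v1.v_g * v2.v_g), -1.0, 1.0))
    return GeneticCorrelation(trait1, trait2, cov_g, r, v1.v_g, v2.v_g)


def standardize_traits(
    t: pd.DataFrame,
    by: list[str] | None = None,
) -> pd.DataFrame:
    """Per-group z-scores of trait values: (x - group mean) / group SD.

    Groups default to (population, trait) when a population column exists,
    else trait alone — each subpopulation is standardized independently, as
    needed before pooling subpopulations or fitting reaction norms.
    """
    if by is None:
        by = ["population", "trait"] if "population" in t.columns else ["trait"]
    out = t.copy()

    def z(s: pd.Series) -> pd.Series:
        sd = s.std(ddof=1)
        if not np.isfinite(sd) or sd == 0:
            raise ValueError(f"zero variance in group {s.name!r}: cannot standardize")
        return (s - s.mean()) / sd

    out["value"] = out.groupby(by, group_keys=False)["value"].apply(z)
    return out


def reaction_norm(
    t: pd.DataFrame,
    trait: str,
    environments: tuple[str, str] = ("autumn", "winter"),
) -> pd.DataFrame:
    """Per-genotype least-squares line across two environments.

    Expects standardized values (see :func:`standardize_traits`).  With
    environments coded 0 and 1, the least-squares line through the two
    environment means has intercept = mean(env0) and slope =
    mean(env1) - mean(env0).  Genotypes observed in a single environment are
    excluded (flagged in the ``excluded`` attribute of the result).
    """
    if "environment" not in t.columns:
        raise ValueError("reaction norms need an 'environment' column")
    sub = _trait_values(t, trait)
    sub = sub[sub["environment"].isin(environments)]
    means = sub.pivot_table(index="genotype", columns="environment",
                            values="value", aggfunc="mean")
    complete = means.dropna(subset=list(environments))
    out = pd.DataFrame({
        "genotype": complete.index,
        "mean_env0": complete[environments[0]].to_numpy(),
        "mean_env1": complete[environments[1]].to_numpy(),
    })
    out["intercept"] = out["mean_env0"]
    out["slope"] = out["mean_env1"] - out["mean_env0"]
    out.attrs["excluded"] = sorted(set(means.index) - set(complete.index))
    return out.reset_index(drop=True)


def heritability_table(
    t: pd.DataFrame,
    traits: list[str],
    standardize: bool = False,
) -> pd.DataFrame:
    """H^2 / CV_G summary for several traits (one row per trait).

    ``standardize`` applies per-(population, trait) z-scoring first — used
    when pooling subpopulations into an entire-population estimate, where
    CV_G is then meaningless and reported as NaN.
    """
    data = standardize_traits(t) if standardize else t
    rows = []
    for trait in traits:
        est = estimate_heritability(data, trait)
        rows.append({
            "trait": trait,
            "H2": est.h2,
            "CV_G": np.nan if (standardize or est.cv_g is None) else est.cv_g,
            "V_G": est.v_g,
            "V_E": est.v_e,
        })
    return pd.DataFrame(rows)
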