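import numpy as np
import pandas as pd
import pytest

from petalmorph.quantgen import (
    anova_components,
    broad_sense_heritability,
    estimate_heritability,
    genetic_correlation,
    heritability_table,
    reaction_norm,
    standardize_traits,
)
from petalmorph.synthetic_fixtures import PopulationSpec, simulate_clonal_population


def table(genotypes, values, trait="t", **extra):
    if isinstance(genotypes, str):
        genotypes = list(genotypes)
    df = pd.DataFrame({"genotype": genotypes, "trait": trait, "value": values})
    for k, v in extra.items():
        df[k] = v
    return df


def brute_force_components(df, trait):
    """Independent oracle: explicit double-loop sums of squares."""
    sub = df[df["trait"] == trait]
    groups = {g: s["value"].to_numpy() for g, s in sub.groupby("genotype")}
    grand = sub["value"].mean()
    ss_a = ss_w = 0.0
    for vals in groups.values():
        ss_a += len(vals) * (vals.mean() - grand) ** 2
        for v in vals:
            ss_w += (v - vals.mean()) ** 2
    n_gen = len(groups)
    n_tot = sum(len(v) for v in groups.values())
    return ss_a / (n_gen - 1), ss_w / (n_tot - n_gen), n_tot / n_gen


class TestAnovaComponents:
    def test_hand_worked_two_genotype_example(self):
        vc = anova_components(table("AABB", [1, 3, 5, 7]), "t")
        assert vc.ms_among == pytest.approx(16.0)
        assert vc.ms_within == pytest.approx(2.0)
        assert vc.n_bar == pytest.approx(2.0)
        assert vc.v_e == pytest.approx(2.0)
        assert vc.v_g == pytest.approx(7.0)

    def test_zero_within_variance(self):
        vc = anova_components(table("AABB", [2, 2, 9, 9]), "t")
        assert vc.v_e == 0.0
        assert vc.v_g > 0

    def test_no_genetic_signal_clamped(self):
        rng = np.random.default_rng(0)
        g = np.repeat(list("ABCDE"), 4)
        vc = anova_components(table(g, 5 + 0.01 * rng.normal(size=20)), "t")
        if vc.ms_among <= vc.ms_within:
            assert vc.v_g == 0.0 and vc.clamped

    def test_matches_brute_force_oracle_unbalanced(self):
        rng = np.random.default_rng(3)
        g = ["A"] * 3 + ["B"] * 5 + ["C"] * 2 + ["D"] * 6
        df = table(g, rng.normal(10, 2, len(g)))
        vc = anova_components(df, "t")
        ms_a, ms_w, n_bar = brute_force_components(df, "t")
        assert vc.ms_among == pytest.approx(ms_a, rel=1e-9)
        assert vc.ms_within == pytest.approx(ms_w, rel=1e-9)
        assert vc.n_bar == pytest.approx(n_bar)

    def test_all_singletons_rejected(self):
        with pytest.raises(ValueError, match="single observation"):
            anova_components(table("ABC", [1, 2, 3]), "t")

    def test_fewer_than_two_genotypes_rejected(self):
        with pytest.raises(ValueError):
            anova_components(table("AAA", [1, 2, 3]), "t")


class TestHeritability:
    def test_continues_hand_example(self):
        est = estimate_heritability(table("AABB", [1, 3, 5, 7]), "t")
        assert est.h2 == pytest.approx(7 / 9)
        assert est.cv_g == pytest.approx(100 * np.sqrt(7) / 4)

    def test_zero_genetic_variance(self):
        est = estimate_heritability(table("AABB", [1, 3, 3, 1]), "t")
        assert est.h2 == 0.0

    def test_affine_invariance_of_h2_not_cvg(self):
        rng = np.random.default_rng(4)
        g = np.repeat([f"g{i}" for i in range(10)], 4)
        vals = rng.normal(10, 1, 40) + np.repeat(rng.normal(0, 2, 10), 4)
        e1 = estimate_heritability(table(g, vals), "t")
        e2 = estimate_heritability(table(g, 3.0 * vals + 7.0), "t")
        assert e2.h2 == pytest.approx(e1.h2, rel=1e-9)
        assert e2.cv_g != pytest.approx(e1.cv_g, rel=1e-3)

    def test_recovery_unbiased_quickcheck(self):
        # 100-seed Monte-Carlo at the paper-scale design (full 500-seed sweep
        # in the acceptance tests)
        est = []
        for s in range(100):
            spec = PopulationSpec(n_genotypes=60, n_replicates=6, traits=("x",),
                                  mu=(10.0,), sd_g=(1.0,), sd_e=(1.0,))
            t, truth = simulate_clonal_population(spec, seed=100 + s)
            est.append(estimate_heritability(t, "x").h2)
            assert truth["h2"]["x"] == pytest.approx(0.5)
        assert np.mean(est) == pytest.approx(0.5, abs=0.05)

    def test_zero_residual_variance_gives_h2_one(self):
        spec = PopulationSpec(n_genotypes=10, n_replicates=4, traits=("x",),
                              mu=(5.0,), sd_g=(1.0,), sd_e=(0.0,))
        t, _ = simulate_clonal_population(spec, seed=1)
        assert estimate_heritability(t, "x").h2 == 1.0


class TestGeneticCorrelation:
    def _two_trait_table(self, rng, n_gen=30, n_rep=4):
        g = np.repeat([f"g{i}" for i in range(n_gen)], n_rep)
        G = np.repeat(rng.normal(0, 2, n_gen), n_rep)
        x = 10 + G + rng.normal(0, 1, len(g))
        return g, x

    def test_self_correlation_is_one(self):
        rng = np.random.default_rng(5)
        g, x = self._two_trait_table(rng)
        df = pd.concat([
            table(g, x, trait="a", replicate=np.tile(np.arange(4), 30)),
            table(g, x, trait="b", replicate=np.tile(np.arange(4), 30)),
        ])
        assert genetic_correlation(df, "a", "b").r_g == pytest.approx(1.0)

    def test_negated_trait_gives_minus_one(self):
        rng = np.random.default_rng(6)
        g, x = self._two_trait_table(rng)
        df = pd.concat([
            table(g, x, trait="a", replicate=np.tile(np.arange(4), 30)),
            table(g, -x, trait="b", replicate=np.tile(np.arange(4), 30)),
        ])
        assert genetic_correlation(df, "a", "b").r_g == pytest.approx(-1.0)

    def test_monte_carlo_recovery_quickcheck(self):
        est = []
        for s in range(40):
            spec = PopulationSpec(n_genotypes=200, n_replicates=8,
                                  traits=("a", "b"), mu=(10.0, 5.0),
                                  sd_g=(1.0, 0.8), sd_e=(1.0, 0.8),
                                  corr=np.array([[1.0, 0.6], [0.6, 1.0]]))
            t, _ = simulate_clonal_population(spec, seed=300 + s)
            est.append(genetic_correlation(t, "a", "b").r_g)
        assert np.mean(est) == pytest.approx(0.6, abs=0.05)

    def test_zero_vg_reported_missing(self):
        df = pd.concat([
            table("AABB", [1, 2, 1, 2], trait="a", replicate=[0, 1, 0, 1]),
            table("AABB", [5, 6, 5, 6], trait="b", replicate=[0, 1, 0, 1]),
        ])
        r = genetic_correlation(df, "a", "b")
        assert r.r_g is None

    def test_genotype_means_mode_runs(self):
        rng = np.random.default_rng(7)
        g, x = self._two_trait_table(rng)
        df = pd.concat([
            table(g, x, trait="a", replicate=np.tile(np.arange(4), 30)),
            table(g, x + rng.normal(0, 0.1, len(g)), trait="b",
                  replicate=np.tile(np.arange(4), 30)),
        ])
        r = genetic_correlation(df, "a", "b", method="genotype_means")
        assert 0.9 < r.r_g <= 1.0


class TestStandardize:
    def test_zero_mean_unit_sd_per_group(self):
        rng = np.random.default_rng(8)
        df = pd.concat([
            table(list("ABCD") * 5, rng.normal(50, 9, 20), population="standard"),
            table(list("EFGH") * 5, rng.normal(5, 1, 20), population="spray"),
        ])
        z = standardize_traits(df)
        for _, sub in z.groupby("population"):
            assert sub["value"].mean() == pytest.approx(0.0, abs=1e-10)
            assert sub["value"].std(ddof=1) == pytest.approx(1.0, abs=1e-10)

    def test_affine_invariance(self):
        rng = np.random.default_rng(9)
        vals = rng.normal(size=12)
        df1 = table(list("ABC") * 4, vals)
        df2 = table(list("ABC") * 4, 5 * vals - 2)
        assert np.allclose(standardize_traits(df1)["value"],
                           standardize_traits(df2)["value"])

    def test_constant_group_rejected(self):
        with pytest.raises(ValueError, match="zero variance"):
            standardize_traits(table("AB", [3.0, 3.0]))


class TestReactionNorm:
    def _env_table(self, auts, wins):
        rows = []
        for g in auts:
            rows += [{"genotype": g, "trait": "t", "value": auts[g],
                      "environment": "autumn"}]
        for g in wins:
            rows += [{"genotype": g, "trait": "t", "value": wins[g],
                      "environment": "winter"}]
        return pd.DataFrame(rows)

    def test_identical_means_zero_slope(self):
        df = self._env_table({"g1": 0.3}, {"g1": 0.3})
        out = reaction_norm(df, "t")
        assert out.loc[0, "slope"] == pytest.approx(0.0)

    def test_two_point_slope(self):
        df = self._env_table({"g1": -1.0}, {"g1": 1.0})
        out = reaction_norm(df, "t")
        assert out.loc[0, "slope"] == pytest.approx(2.0)
        assert out.loc[0, "intercept"] == pytest.approx(-1.0)

    def test_single_environment_genotype_excluded(self):
        df = self._env_table({"g1": 0.0, "g2": 1.0}, {"g1": 0.5})
        out = reaction_norm(df, "t")
        assert list(out["genotype"]) == ["g1"]
        assert out.attrs["excluded"] == ["g2"]

    def test_simulated_gxe_slopes_recovered_noise_free(self):
        spec = PopulationSpec(n_genotypes=8, n_replicates=4, traits=("x",),
                              mu=(10.0,), sd_g=(1.0,), sd_e=(0.0,),
                              env_shift={"autumn": 0.0, "winter": 2.0},
                              gxe_sd=0.3)
        t, truth = simulate_clonal_population(spec, seed=11)
        out = reaction_norm(t, "x").set_index("genotype")
        for g, slope in truth["slopes"].items():
            assert out.loc[g, "slope"] == pytest.approx(slope, abs=1e-9)


class TestHeritabilityTable:
    def test_two_trait_summary(self):
        spec = PopulationSpec(n_genotypes=40, n_replicates=5)
        t, truth = simulate_clonal_population(spec, seed=21)
        res = heritability_table(t, ["area", "convexity"]).set_index("trait")
        assert 0 <= res.loc["area", "H2"] <= 1
        assert res.loc["area", "CV_G"] > 0
        pooled = heritability_table(t, ["area"], standardize=True)
        assert np.isnan(pooled.loc[0, "CV_G"])
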