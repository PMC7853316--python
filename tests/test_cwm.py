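import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

import gradient_niche as gn
from gradient_niche.cwm import ModelDataError, fit_cwm_gradient_model
from oracles import brute_cwm, sequential_anova_ss


def make_tables(counts_by_plot, trait_values):
    plots = [f"p{i}" for i in range(len(counts_by_plot))]
    species = [f"s{j}" for j in range(len(trait_values))]
    abund = gn.AbundanceMatrix(pd.DataFrame(counts_by_plot, index=plots,
                                            columns=species))
    traits = gn.TraitTable(pd.DataFrame({"shell_size": trait_values},
                                        index=pd.Index(species, name="species")))
    return abund, traits


class TestCommunityWeightedMean:
    def test_single_species_equals_its_trait(self):
        abund, traits = make_tables([[7]], [4.2])
        cwm = gn.community_weighted_mean(abund, traits, "shell_size")
        assert cwm["p0"] == pytest.approx(4.2)

    def test_equal_abundance_of_two_species_averages_traits(self):
        abund, traits = make_tables([[5, 5]], [2.0, 4.0])
        cwm = gn.community_weighted_mean(abund, traits, "shell_size")
        assert cwm["p0"] == pytest.approx(3.0)

    def test_hand_weighted_example(self):
        abund, traits = make_tables([[1, 2, 3]], [10.0, 20.0, 30.0])
        cwm = gn.community_weighted_mean(abund, traits, "shell_size")
        assert cwm["p0"] == pytest.approx(140 / 6)

    def test_empty_plot_flagged_nan(self):
        abund, traits = make_tables([[1, 1], [0, 0]], [2.0, 4.0])
        cwm = gn.community_weighted_mean(abund, traits, "shell_size")
        assert np.isnan(cwm["p1"])

    def test_species_without_trait_excluded_and_weights_renormalized(self):
        abund, traits = make_tables([[2, 2, 2]], [3.0, 9.0, np.nan])
        cwm = gn.community_weighted_mean(abund, traits, "shell_size")
        assert cwm["p0"] == pytest.approx(6.0)

    @given(st.data())
    def test_matches_brute_force_and_stays_in_trait_range(self, data):
        n_sp = data.draw(st.integers(1, 6))
        counts = data.draw(st.lists(st.integers(0, 20), min_size=n_sp, max_size=n_sp))
        traits = data.draw(st.lists(
            st.floats(0.1, 50, allow_nan=False), min_size=n_sp, max_size=n_sp))
        abund, tt = make_tables([counts], traits)
        cwm = gn.community_weighted_mean(abund, tt, "shell_size")["p0"]
        if sum(counts) == 0:
            assert np.isnan(cwm)
            return
        assert cwm == pytest.approx(brute_cwm(traits, counts))
        present = [t for t, c in zip(traits, counts) if c > 0]
        assert min(present) - 1e-9 <= cwm <= max(present) + 1e-9

    def test_invariant_to_scaling_plot_abundances(self):
        abund, traits = make_tables([[1, 2, 3]], [10.0, 20.0, 30.0])
        scaled, _ = make_tables([[5, 10, 15]], [10.0, 20.0, 30.0])
        a = gn.community_weighted_mean(abund, traits, "shell_size")["p0"]
        b = gn.community_weighted_mean(scaled, traits, "shell_size")["p0"]
        assert a == pytest.approx(b)


def env_from(regions, lui):
    plots = [f"p{i}" for i in range(len(lui))]
    return gn.EnvironmentTable(pd.DataFrame({
        "region": regions, "habitat": ["grassland"] * len(lui), "LUI": lui,
    }, index=pd.Index(plots, name="plot_id")))


class TestGradientModel:
    def test_constant_cwm_gives_zero_term_ss(self):
        rng = np.random.default_rng(0)
        env = env_from(["ALB"] * 20, rng.uniform(1, 4, 20))
        cwm = pd.Series(5.0, index=env.plots, name="shell_size")
        res = fit_cwm_gradient_model(cwm, env, "LUI")
        # nothing to explain: every term's SS is numerically zero
        assert res.table.drop(index="Residual")["sum_sq"].abs().max() < 1e-18
        assert res.table.loc["Residual", "sum_sq"] == pytest.approx(0.0, abs=1e-18)

    def test_perfect_linear_fit_single_region(self):
        env = env_from(["ALB"] * 10, np.linspace(1, 4, 10))
        cwm = pd.Series(2.0 * env.data["LUI"].to_numpy(), index=env.plots,
                        name="shell_size")
        res = fit_cwm_gradient_model(cwm, env, "LUI")
        total = res.table["sum_sq"].sum()
        assert res.table.loc["LUI", "sum_sq"] == pytest.approx(total)
        assert res.table.loc["Residual", "sum_sq"] == pytest.approx(0.0, abs=1e-16)

    def test_sequential_ss_match_projection_oracle(self):
        rng = np.random.default_rng(42)
        n = 30
        regions = np.repeat(["ALB", "HAI", "SCH"], n // 3)
        lui = rng.uniform(0.53, 4.52, n)
        offsets = {"ALB": 0.0, "HAI": 1.5, "SCH": -0.8}
        y = (1.2 * lui + np.array([offsets[r] for r in regions])
             + rng.normal(0, 0.3, n))
        env = env_from(list(regions), lui)
        cwm = pd.Series(y, index=env.plots, name="shell_size")
        res = fit_cwm_gradient_model(cwm, env, "LUI")

        d_hai = (regions == "HAI").astype(float)
        d_sch = (regions == "SCH").astype(float)
        blocks = [lui.reshape(-1, 1),
                  np.column_stack([d_hai, d_sch]),
                  np.column_stack([lui * d_hai, lui * d_sch])]
        ss, resid = sequential_anova_ss(y, blocks)
        for term, expected in zip(["LUI", "region", "LUI:region"], ss):
            assert res.table.loc[term, "sum_sq"] == pytest.approx(expected, rel=1e-8)
        assert res.table.loc["Residual", "sum_sq"] == pytest.approx(resid, rel=1e-8)

    def test_sequential_ss_sum_to_total_and_f_nonnegative(self):
        rng = np.random.default_rng(7)
        for _ in range(10):
            n = int(rng.integers(12, 30))
            regions = list(rng.choice(["ALB", "HAI"], n))
            if len(set(regions)) < 2:
                regions[0] = "ALB"; regions[1] = "HAI"
            env = env_from(regions, rng.uniform(1, 4, n))
            y = rng.normal(0, 1, n)
            cwm = pd.Series(y, index=env.plots, name="t")
            res = fit_cwm_gradient_model(cwm, env, "LUI")
            total = float(((y - y.mean()) ** 2).sum())
            assert res.table["sum_sq"].sum() == pytest.approx(total, rel=1e-9)
            assert (res.table["F"].dropna() >= 0).all()

    def test_sqrt_transform_applied_to_grazing(self):
        rng = np.random.default_rng(1)
        plots = [f"p{i}" for i in range(24)]
        grazing = rng.uniform(0, 800, 24)
        env = gn.EnvironmentTable(pd.DataFrame({
            "region": ["ALB"] * 24, "habitat": ["grassland"] * 24,
            "grazing": grazing}, index=pd.Index(plots, name="plot_id")))
        y = 0.1 * np.sqrt(grazing)  # exactly linear on the sqrt scale
        res = fit_cwm_gradient_model(pd.Series(y, index=env.plots, name="t"),
                                     env, "grazing")
        assert res.transform == "sqrt"
        assert res.table.loc["Residual", "sum_sq"] == pytest.approx(0.0, abs=1e-16)

    def test_too_few_plots_fails_with_deficit(self):
        env = env_from(["ALB", "ALB", "HAI"], [1.0, 2.0, 3.0])
        cwm = pd.Series([1.0, 2.0, 3.0], index=env.plots, name="t")
        with pytest.raises(ModelDataError, match="parameters"):
            fit_cwm_gradient_model(cwm, env, "LUI")


class TestHabitatRegionComparison:
    @staticmethod
    def two_habitat_env(values_forest, values_grass, regions=("ALB", "HAI")):
        rows = []
        cwm = {}
        k = 0
        for region in regions:
            for habitat, vals in (("forest", values_forest),
                                  ("grassland", values_grass)):
                for v in vals:
                    pid = f"p{k}"; k += 1
                    rows.append({"plot_id": pid, "region": region,
                                 "habitat": habitat, "pH": 5.0})
                    cwm[pid] = v
        env = gn.EnvironmentTable(pd.DataFrame(rows).set_index("plot_id"))
        return env, pd.Series(cwm, name="t")

    def test_identical_habitat_distributions_not_significant(self):
        vals = list(np.linspace(1, 3, 8))
        env, cwm = self.two_habitat_env(vals, vals)
        rep = gn.compare_cwm_habitat_region(cwm, env)
        for region, (F, p) in rep.habitat_tests.items():
            assert F == pytest.approx(0.0, abs=1e-12)
            assert p == pytest.approx(1.0)

    def test_large_habitat_shift_significant_everywhere(self):
        rng = np.random.default_rng(3)
        forest = list(10 + rng.normal(0, 0.1, 10))
        grass = list(rng.normal(0, 0.1, 10))
        env, cwm = self.two_habitat_env(forest, grass)
        rep = gn.compare_cwm_habitat_region(cwm, env)
        assert rep.habitat_tests and all(
            p < 0.001 for _, p in rep.habitat_tests.values())

    def test_identical_regions_tukey_not_significant(self):
        vals = list(np.linspace(1, 3, 8))
        env, cwm = self.two_habitat_env(vals, vals)
        rep = gn.compare_cwm_habitat_region(cwm, env)
        for frame in rep.region_tests.values():
            assert (np.array(frame["p-adj"], dtype=float) > 0.9).all()

    def test_single_habitat_region_skipped_with_notice(self):
        rows = [{"plot_id": f"p{i}", "region": "ALB", "habitat": "forest",
                 "pH": 5.0} for i in range(6)]
        env = gn.EnvironmentTable(pd.DataFrame(rows).set_index("plot_id"))
        cwm = pd.Series(np.linspace(1, 2, 6), index=env.plots, name="t")
        rep = gn.compare_cwm_habitat_region(cwm, env)
        assert "ALB" in rep.skipped
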