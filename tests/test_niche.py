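import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

import gradient_niche as gn
from gradient_niche.niche import (
    NicheEstimate,
    NullDistribution,
    NullModelError,
    nearest_rank_quantile,
    niche_estimate,
    null_model,
    species_rng,
)
from oracles import brute_awm, brute_awsd, enumerate_null_awm


def one_species(lui_values, counts, regions=None, name="sp"):
    plots = [f"p{i}" for i in range(len(lui_values))]
    env = gn.EnvironmentTable(pd.DataFrame({
        "region": regions or ["ALB"] * len(plots),
        "habitat": ["grassland"] * len(plots),
        "LUI": lui_values,
    }, index=pd.Index(plots, name="plot_id")))
    abund = gn.AbundanceMatrix(pd.DataFrame({name: counts}, index=env.plots))
    return env, abund


class TestWeightedStatistics:
    def test_single_site_species(self):
        env, ab = one_species([2.5, 3.0], [4, 0])
        assert gn.abundance_weighted_mean(ab, env, "sp", "LUI") == 2.5
        assert gn.abundance_weighted_sd(ab, env, "sp", "LUI") == 0.0

    def test_equal_abundance_two_sites(self):
        env, ab = one_species([1.0, 3.0], [5, 5])
        assert gn.abundance_weighted_mean(ab, env, "sp", "LUI") == pytest.approx(2.0)
        assert gn.abundance_weighted_sd(ab, env, "sp", "LUI") == pytest.approx(1.0)

    def test_hand_weighted_example(self):
        env, ab = one_species([0.0, 4.0], [1, 3])
        assert gn.abundance_weighted_mean(ab, env, "sp", "LUI") == pytest.approx(3.0)
        assert gn.abundance_weighted_sd(ab, env, "sp", "LUI") == pytest.approx(np.sqrt(3))

    def test_absent_species_raises(self):
        env, ab = one_species([1.0], [1])
        with pytest.raises(KeyError):
            gn.abundance_weighted_mean(ab, env, "ghost", "LUI")

    @given(st.data())
    def test_matches_brute_force_loops(self, data):
        n = data.draw(st.integers(1, 10))
        lui = data.draw(st.lists(st.floats(0.5, 4.5, allow_nan=False),
                                 min_size=n, max_size=n))
        counts = data.draw(st.lists(st.integers(0, 30), min_size=n, max_size=n))
        if sum(counts) == 0:
            counts[0] = 1
        env, ab = one_species(lui, counts)
        occ_l = [v for v, c in zip(lui, counts) if c > 0]
        occ_c = [c for c in counts if c > 0]
        assert gn.abundance_weighted_mean(ab, env, "sp", "LUI") == pytest.approx(
            brute_awm(occ_l, occ_c))
        assert gn.abundance_weighted_sd(ab, env, "sp", "LUI") == pytest.approx(
            brute_awsd(occ_l, occ_c), abs=1e-12)

    def test_awm_bounded_by_occupied_gradient_range(self):
        env, ab = one_species([1.0, 2.0, 4.0], [3, 5, 2])
        est = niche_estimate(ab, env, "sp", "LUI")
        assert 1.0 <= est.awm <= 4.0
        assert est.n_sites == 3

    def test_cv_undefined_when_awm_zero(self):
        env, ab = one_species([0.0, 0.0], [2, 3])
        env.data["LUI"] = [0.0, 0.0]
        est = niche_estimate(ab, env, "sp", "LUI")
        assert est.awm == 0.0 and not est.cv_defined


class TestNullModel:
    def test_fixed_seed_reproduces_draws(self):
        env, ab = one_species([1.0, 2.0, 3.0, 4.0], [2, 0, 1, 0])
        a = null_model(ab, env, "sp", "LUI", n_iter=500, seed=3)
        b = null_model(ab, env, "sp", "LUI", n_iter=500, seed=3)
        assert np.array_equal(a.awm_draws, b.awm_draws)

    def test_draws_confined_to_regional_pool_range(self):
        lui = [1.0, 1.5, 2.0, 3.5, 4.0, 4.5]
        regions = ["ALB", "ALB", "ALB", "HAI", "HAI", "HAI"]
        env, ab = one_species(lui, [1, 2, 0, 0, 0, 0], regions=regions)
        null = null_model(ab, env, "sp", "LUI", n_iter=1000, seed=1)
        # species recorded only in ALB: null must never sample HAI plots
        assert null.pool_size == 3
        assert null.awm_draws.min() >= 1.0 and null.awm_draws.max() <= 2.0

    def test_degenerate_null_everything_occupied_equal_abundance(self):
        env, ab = one_species([1.0, 2.0, 3.0], [4, 4, 4])
        null = null_model(ab, env, "sp", "LUI", n_iter=200, seed=0)
        assert np.allclose(null.awm_draws, null.observed.awm)
        cls = gn.classify_response(null.observed, null)
        assert cls.status == "neutral"

    def test_inconsistent_gradient_coverage_rejected(self):
        # gradient undefined on an occupied plot: the region-restricted pool
        # cannot be formed consistently
        env, ab = one_species([1.0, 2.0], [1, 1])
        env.data.loc["p1", "LUI"] = np.nan
        with pytest.raises(NullModelError, match="undefined"):
            null_model(ab, env, "sp", "LUI", n_iter=10, seed=0)

    def test_tails_match_exhaustive_enumeration_equal_abundance(self):
        """4-site pool, 2 occupied sites: exact null is the 6 site pairs."""
        lui = [1.0, 2.0, 3.0, 4.0]
        env, ab = one_species(lui, [3, 0, 0, 3])
        null = null_model(ab, env, "sp", "LUI", n_iter=10_000, seed=5)
        exact = enumerate_null_awm(lui, [3, 3])
        obs = null.observed.awm
        for p_mc, p_ex in ((null.p_high, (exact >= obs).mean()),
                           (null.p_low, (exact <= obs).mean())):
            se = np.sqrt(p_ex * (1 - p_ex) / null.n_iter)
            assert abs(p_mc - p_ex) <= 3 * se + 1e-12

    def test_tails_match_enumeration_unequal_abundances(self):
        lui = [0.6, 1.1, 1.9, 2.8, 3.3, 4.2]
        env, ab = one_species(lui, [5, 0, 1, 0, 2, 0])
        null = null_model(ab, env, "sp", "LUI", n_iter=10_000, seed=6)
        exact = enumerate_null_awm(lui, [5, 1, 2])
        obs = null.observed.awm
        p_ex = (exact >= obs).mean()
        se = np.sqrt(p_ex * (1 - p_ex) / null.n_iter)
        assert abs(null.p_high - p_ex) <= 3 * se

    def test_presence_weighting_ignores_abundances(self):
        env, ab = one_species([1.0, 2.0, 3.0, 4.0], [9, 0, 1, 0])
        null = null_model(ab, env, "sp", "LUI", n_iter=2000, seed=2,
                          weighting="presence")
        # equal weights on 2 of 4 sites: only pairwise means can occur
        means = {np.mean(pair) for pair in
                 [(1, 2), (1, 3), (1, 4), (2, 3), (2, 4), (3, 4)]}
        assert set(np.round(np.unique(null.awm_draws), 9)) <= {
            round(m, 9) for m in means}


def synthetic_null(obs_awm, obs_cv, draws_awm, draws_cv, species="x", gradient="LUI"):
    obs = NicheEstimate(species=species, gradient=gradient, awm=obs_awm,
                        awsd=obs_cv * obs_awm, cv=obs_cv, n_sites=5,
                        regions=("ALB",))
    return obs, NullDistribution(
        species=species, gradient=gradient, n_iter=len(draws_awm),
        awm_draws=np.asarray(draws_awm, dtype=float),
        awsd_draws=np.asarray(draws_cv, dtype=float) * np.asarray(draws_awm, dtype=float),
        cv_draws=np.asarray(draws_cv, dtype=float), observed=obs, pool_size=10)


class TestClassification:
    def test_observation_above_every_draw_is_winner(self):
        rng = np.random.default_rng(0)
        obs, null = synthetic_null(5.0, 0.3, rng.uniform(1, 2, 1000),
                                   rng.uniform(0.2, 0.5, 1000))
        cls = gn.classify_response(obs, null)
        assert cls.status == "winner"
        assert cls.p_value <= 1 / null.n_iter

    def test_observation_below_every_draw_is_loser(self):
        rng = np.random.default_rng(0)
        obs, null = synthetic_null(0.5, 0.3, rng.uniform(1, 2, 1000),
                                   rng.uniform(0.2, 0.5, 1000))
        assert gn.classify_response(obs, null).status == "loser"

    def test_intermediate_awm_with_narrow_cv_is_mid_specialist(self):
        rng = np.random.default_rng(0)
        obs, null = synthetic_null(1.5, 0.05, rng.uniform(1, 2, 1000),
                                   rng.uniform(0.2, 0.5, 1000))
        assert gn.classify_response(obs, null).status == "mid-specialist"

    def test_single_site_species_cannot_be_mid_specialist(self):
        rng = np.random.default_rng(0)
        obs, null = synthetic_null(1.5, 0.0, rng.uniform(1, 2, 1000),
                                   rng.uniform(0.2, 0.5, 1000))
        assert gn.classify_response(obs, null).status == "neutral"

    def test_abiotic_gradient_uses_low_high_labels(self):
        rng = np.random.default_rng(0)
        obs, null = synthetic_null(9.0, 0.3, rng.uniform(4, 6, 1000),
                                   rng.uniform(0.2, 0.5, 1000), gradient="pH")
        assert gn.classify_response(obs, null).status == "high"

    def test_nearest_rank_quantile_definition(self):
        draws = np.arange(1.0, 101.0)  # 1..100
        assert nearest_rank_quantile(draws, 0.95) == 95.0
        assert nearest_rank_quantile(draws, 0.05) == 5.0


class TestHypervolume:
    def test_unit_components_give_unit_volume(self):
        comps = {g: 1.0 for g in ("mowing", "grazing", "fertilization", "pH", "moisture")}
        assert gn.niche_hypervolume(comps, "grassland", species="x").value == 1.0

    def test_product_of_components(self):
        comps = dict(zip(("Inonat", "Idwcut", "Iharv", "pH", "moisture"),
                         (2.0, 0.5, 3.0, 1.0, 2.0)))
        assert gn.niche_hypervolume(comps, "forest", species="x").value == pytest.approx(6.0)

    def test_zero_if_any_component_zero(self):
        comps = {g: 1.0 for g in ("Inonat", "Idwcut", "Iharv", "pH", "moisture")}
        comps["pH"] = 0.0
        assert gn.niche_hypervolume(comps, "forest", species="x").value == 0.0

    def test_permutation_invariant_and_linear_in_each_component(self):
        names = ("mowing", "grazing", "fertilization", "pH", "moisture")
        vals = (1.5, 2.0, 0.5, 3.0, 1.2)
        base = gn.niche_hypervolume(dict(zip(names, vals)), "grassland", species="x")
        shuffled = gn.niche_hypervolume(
            dict(zip(names, vals[::-1])), "grassland", species="x")
        assert base.value == pytest.approx(shuffled.value)
        doubled = dict(zip(names, vals)); doubled["pH"] *= 2
        assert gn.niche_hypervolume(doubled, "grassland", species="x").value == \
            pytest.approx(2 * base.value)

    def test_missing_component_named(self):
        comps = {g: 1.0 for g in ("Inonat", "Idwcut", "pH", "moisture")}
        with pytest.raises(KeyError, match="Iharv"):
            gn.niche_hypervolume(comps, "forest", species="x")


@pytest.fixture(scope="module")
def grass_data():
    config = gn.ScenarioConfig(seed=13, n_species=12)
    env, ab, _, rl, _ = gn.generate_dataset(config)
    genv = env.subset(habitat="grassland")
    gab = ab.subset_plots(genv.plots).drop_empty_species()
    return genv, gab, rl


class TestSpeciesResponseTable:

    def test_shape_and_columns(self, grass_data):
        env, ab, rl = grass_data
        table = gn.species_response_table(ab, env, ["LUI", "pH"], redlist=rl,
                                          n_iter=300, seed=1)
        assert len(table) == len(ab.species)
        assert {"redlist", "regions", "occurrence", "abundance",
                "LUI", "pH"} <= set(table.columns)
        valid = set(gn.niche.LANDUSE_STATUSES) | set(gn.niche.ABIOTIC_STATUSES)
        assert set(table["LUI"]) <= valid and set(table["pH"]) <= valid

    def test_deterministic_under_fixed_seed(self, grass_data):
        env, ab, rl = grass_data
        a = gn.species_response_table(ab, env, ["LUI"], n_iter=300, seed=2)
        b = gn.species_response_table(ab, env, ["LUI"], n_iter=300, seed=2)
        pd.testing.assert_frame_equal(a, b)

    def test_invariant_to_plot_row_order(self, grass_data):
        env, ab, rl = grass_data
        a = gn.species_response_table(ab, env, ["LUI"], n_iter=300, seed=2)
        perm = np.random.default_rng(0).permutation(len(env.plots))
        env2 = gn.EnvironmentTable(env.data.iloc[perm].copy())
        ab2 = gn.AbundanceMatrix(ab.counts.iloc[perm].copy())
        b = gn.species_response_table(ab2, env2, ["LUI"], n_iter=300, seed=2)
        pd.testing.assert_frame_equal(a, b.loc[a.index])

    def test_removing_one_species_leaves_others_unchanged(self, grass_data):
        env, ab, rl = grass_data
        a = gn.species_response_table(ab, env, ["LUI"], n_iter=300, seed=2)
        dropped = ab.species[0]
        ab2 = gn.AbundanceMatrix(ab.counts.drop(columns=dropped))
        b = gn.species_response_table(ab2, env, ["LUI"], n_iter=300, seed=2)
        pd.testing.assert_frame_equal(a.drop(index=dropped), b)

    def test_substreams_differ_between_species(self):
        a = species_rng(1, "spA", "LUI").random(4)
        b = species_rng(1, "spB", "LUI").random(4)
        assert not np.allclose(a, b)
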