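"""Simulator unit and property tests: trait sampling, production kernel,
mortality, establishment, climate construction, and run-level invariants."""

import numpy as np
import pandas as pd
import pytest

from fdforest.simulator import (DEFAULT_PFTS, PatchState, SimulationConfig,
                                TreeIndividual, annual_production, establish,
                                leaf_longevity_from_sla, make_climate,
                                phenology_activity, run_simulation,
                                sample_traits, substream, survival_step,
                                death_probability)

CFG = SimulationConfig()
BLS = CFG.pft_by_name("BL-S")
TNL = CFG.pft_by_name("T-NL")
BNL = CFG.pft_by_name("B-NL")

WARM_YEAR = np.array([-2, 0, 4, 9, 13, 16, 18, 16, 13, 9, 4, -2], float)
COLD_YEAR = np.full(12, -5.0)


def make_tree(tree_id=0, pft="BL-S", sla=25.0, wd=0.6, height=20.0, age=50.0,
              patch_id=0):
    phen = CFG.pft_by_name(pft).phenology
    return TreeIndividual(
        id=tree_id, patch_id=patch_id, pft=pft, sla=sla,
        leaf_longevity=float(leaf_longevity_from_sla(sla, phen)),
        wood_density=wd, height=height, age=age)


class TestSampleTraits:
    def test_draws_inside_ranges_and_longevity_ordering(self):
        rng = substream(0, "traits")
        for pft in DEFAULT_PFTS:
            sla, ll, wd = sample_traits(pft, rng, size=500)
            assert np.all((sla >= pft.sla_range[0]) & (sla <= pft.sla_range[1]))
            assert np.all((wd >= pft.wd_range[0]) & (wd <= pft.wd_range[1]))
            assert np.all(ll > 0)
        # needle-leaved longevities exceed summergreen at equal percentile
        q = np.linspace(0.05, 0.95, 10)
        sla_b = BNL.sla_range[0] + q * np.ptp(BNL.sla_range)
        sla_s = BLS.sla_range[0] + q * np.ptp(BLS.sla_range)
        assert np.all(leaf_longevity_from_sla(sla_b, BNL.phenology)
                      > leaf_longevity_from_sla(sla_s, BLS.phenology))

    def test_identical_seed_identical_triple(self):
        a = sample_traits(BLS, np.random.default_rng(7))
        b = sample_traits(BLS, np.random.default_rng(7))
        assert a == b

    def test_sla_longevity_strongly_anticorrelated(self):
        rng = np.random.default_rng(1)
        sla, ll, _ = sample_traits(BLS, rng, size=10_000)
        r = np.corrcoef(sla, ll)[0, 1]
        assert r < 0 and abs(r) > 0.9


class TestAnnualProduction:
    def test_light_competition_monotonicity(self):
        lone = make_tree(height=20.0)
        patch = PatchState(0, [lone])
        p_alone = annual_production(lone, patch, WARM_YEAR, CFG)
        shaded_patch = PatchState(0, [lone] + [
            make_tree(tree_id=i + 1, height=30.0) for i in range(10)])
        p_shaded = annual_production(lone, shaded_patch, WARM_YEAR, CFG)
        assert p_alone > p_shaded

    def test_summergreen_gated_off_in_cold_year(self):
        tree = make_tree(pft="BL-S", height=10.0)
        patch = PatchState(0, [tree])
        prod = annual_production(tree, patch, COLD_YEAR, CFG)
        # no gross production: net equals minus maintenance
        assert prod < 0
        assert np.all(phenology_activity(BLS, COLD_YEAR) == 0)

    def test_needles_active_in_shoulder_season_where_summergreen_off(self):
        shoulder = np.array([2.0])
        assert phenology_activity(BLS, shoulder) == 0
        assert phenology_activity(TNL, shoulder) > 0
        warm = np.array([18.0])
        assert phenology_activity(BLS, warm) > phenology_activity(TNL, warm)

    def test_mixed_canopy_raises_understorey_production(self):
        """Phenological complementarity in the production kernel: an
        understorey tree of either phenology produces more under a mixed
        canopy than under an equally dense canopy of a single phenology,
        because activity-weighted shading frees light in the months the
        canopy phenology is inactive."""
        def focal_prod(focal, canopy):
            trees = [focal] + [make_tree(tree_id=100 + i, pft=k, height=h,
                                         sla=s)
                               for i, (k, h, s) in enumerate(canopy)]
            return annual_production(focal, PatchState(0, trees),
                                     WARM_YEAR, CFG)

        canopy_h = [28, 27, 26, 25]
        pure_bls = [("BL-S", h, 25.0) for h in canopy_h]
        pure_tnl = [("T-NL", h, 8.0) for h in canopy_h]
        mixed = [("BL-S", 28, 25.0), ("T-NL", 27, 8.0),
                 ("BL-S", 26, 25.0), ("T-NL", 25, 8.0)]

        focal_bls = make_tree(tree_id=0, pft="BL-S", height=7.0, sla=25.0)
        focal_tnl = make_tree(tree_id=1, pft="T-NL", height=7.0, sla=8.0)
        assert focal_prod(focal_bls, mixed) > focal_prod(focal_bls, pure_bls)
        assert focal_prod(focal_tnl, mixed) > focal_prod(focal_tnl, pure_tnl)

    def test_dead_tree_rejected(self):
        tree = make_tree()
        tree.alive = False
        with pytest.raises(ValueError):
            annual_production(tree, PatchState(0, [tree]), WARM_YEAR, CFG)


class TestSurvivalStep:
    def test_stress_term_vanishes_for_positive_production(self):
        p = death_probability(age=10.0, max_age=350.0, production=2.0,
                              wood_density=0.5, config=CFG)
        expected = CFG.mortality_background + CFG.mortality_age_scale * (
            10.0 / 350.0) ** CFG.mortality_age_exp
        assert p == pytest.approx(expected)

    def test_wood_density_buffers_stress(self):
        p_soft = death_probability(50.0, 350.0, -0.05, 0.4, CFG)
        p_dense = death_probability(50.0, 350.0, -0.05, 0.7, CFG)
        assert p_dense < p_soft

    def test_empirical_death_fraction_matches_hazard(self):
        prod = -0.05  # mild carbon deficit: hazard well inside (0, 1)
        p = float(death_probability(100.0, 350.0, prod, 0.5, CFG))
        assert 0.0 < p < 1.0
        rng = np.random.default_rng(5)
        deaths = sum(not survival_step(make_tree(age=100.0, wd=0.5), prod,
                                       rng, CFG) for _ in range(1000))
        se = np.sqrt(p * (1 - p) / 1000)
        assert abs(deaths / 1000 - p) < 3 * se

    def test_dead_tree_rejected(self):
        tree = make_tree()
        tree.alive = False
        with pytest.raises(ValueError):
            survival_step(tree, 1.0, np.random.default_rng(0), CFG)


class TestEstablish:
    def test_no_establishment_outside_all_bioclimatic_limits(self):
        patch = PatchState(0, [])
        out = establish(patch, np.full(12, 30.0), np.random.default_rng(0),
                        CFG, coldest_month_mean=25.0)
        assert out == []

    def test_closed_canopy_suppresses_establishment(self):
        dense = PatchState(0, [make_tree(tree_id=i, pft="T-NL", sla=8.0,
                                         height=30.0) for i in range(60)])
        rng = np.random.default_rng(3)
        counts = [len(establish(dense, WARM_YEAR, rng, CFG,
                                coldest_month_mean=-2.0)) for _ in range(50)]
        assert np.mean(counts) < 0.25 * CFG.establishment_rate

    def test_bare_ground_rate_matches_poisson_mean(self):
        patch = PatchState(0, [])
        rng = np.random.default_rng(11)
        counts = [len(establish(patch, WARM_YEAR, rng, CFG,
                                coldest_month_mean=-2.0))
                  for _ in range(500)]
        se = np.sqrt(CFG.establishment_rate / 500)
        assert abs(np.mean(counts) - CFG.establishment_rate) < 4 * se


class TestMakeClimate:
    def test_reference_has_no_trend(self):
        slopes = []
        for seed in range(10):
            cfg = SimulationConfig(n_patches=1, seed=seed)
            clim = make_climate("reference", cfg)
            means = clim.annual_means()[cfg.spin_up_years:]
            slopes.append(np.polyfit(np.arange(means.size), means, 1)[0])
        assert abs(np.mean(slopes)) < 0.01

    def test_warming_trend_magnitude(self):
        cfg = SimulationConfig(n_patches=1, seed=4, warming_trend=2.5)
        clim = make_climate("warming", cfg)
        means = clim.annual_means()[cfg.spin_up_years:]
        delta = means[-10:].mean() - means[:10].mean()
        assert delta == pytest.approx(2.25, abs=0.6)

    def test_same_seed_identical_series(self):
        cfg = SimulationConfig(n_patches=1, seed=9)
        a = make_climate("warming", cfg)
        b = make_climate("warming", cfg)
        np.testing.assert_array_equal(a.monthly, b.monthly)

    def test_unknown_scenario_rejected(self):
        with pytest.raises(ValueError):
            make_climate("rcp85", SimulationConfig(n_patches=1))


class TestRunSimulation:
    def test_seeded_bit_reproducibility(self):
        cfg = SimulationConfig(n_patches=10, spin_up_years=30,
                               scenario_years=20, seed=42)
        a = run_simulation(cfg, scenario="reference")
        b = run_simulation(cfg, scenario="reference")
        for year in a.snapshots:
            pd.testing.assert_frame_equal(a.trees_at(year), b.trees_at(year))
            pd.testing.assert_frame_equal(a.patches_at(year),
                                          b.patches_at(year))

    def test_invalid_config_rejected_before_compute(self):
        with pytest.raises(TypeError):
            run_simulation({"n_patches": 3})
        with pytest.raises(ValueError):
            SimulationConfig(n_patches=0)

    def test_trait_immutability_across_snapshots(self, small_run):
        frames = [small_run.trees_at(y) for y in sorted(small_run.snapshots)]
        allt = pd.concat(frames)
        per_id = allt.groupby("tree_id")[
            ["sla", "leaf_longevity", "wood_density"]].nunique()
        assert (per_id == 1).all().all()
        pft_per_id = allt.groupby("tree_id")["pft"].nunique()
        assert (pft_per_id == 1).all()

    def test_heights_grow_and_ids_stable(self, small_run):
        t0 = small_run.trees_at(small_run.t0_year).set_index("tree_id")
        t1 = small_run.trees_at(small_run.t1_year).set_index("tree_id")
        common = t0.index.intersection(t1.index)
        assert len(common) > 0
        assert (t1.loc[common, "height"] >= t0.loc[common, "height"]).all()

    def test_filtering_narrows_within_pft_sla_variance(self, small_run):
        standing = small_run.trees_at(small_run.t0_year)
        est = small_run.establishment_log
        for pft in standing["pft"].unique():
            assert (standing.loc[standing.pft == pft, "sla"].var()
                    < est.loc[est.pft == pft, "sla"].var())

    def test_multiple_height_classes_persist(self, small_run):
        final = small_run.trees_at(small_run.t1_year)
        classes = np.unique((final["height"] // 5).astype(int))
        assert classes.size >= 3

    def test_patch_tables_consistent(self, small_run):
        trees = small_run.trees_at(small_run.t0_year)
        patches = small_run.patches_at(small_run.t0_year)
        counted = trees[trees.height > 5].groupby("patch_id").size()
        for _, row in patches.iterrows():
            assert row["ntrees"] == counted.get(row["patch_id"], 0)
        assert (patches["veg_c"] >= 0).all()


class TestComplementarity:
    def test_mixed_phenology_patches_boost_understorey_survival(self):
        """Phenological complementarity must emerge from the production and
        survival kernels, not be hard-coded: understorey trees in mixed
        broadleaf/needle patches survive 50 years better than in
        density-matched pure broadleaf patches."""
        from conftest import build_mixed_pure_patches

        n_rep = 150
        init = build_mixed_pure_patches(n_rep, seed=107)
        cfg = SimulationConfig(n_patches=2 * n_rep, spin_up_years=0,
                               scenario_years=50, seed=3)
        res = run_simulation(cfg, scenario="reference", initial_trees=init)
        t0 = res.trees_at(0)
        alive = set(res.trees_at(res.t1_year)["tree_id"])
        under = t0[t0.height < 10]
        surv = under["tree_id"].isin(alive)
        pure = under["patch_id"] < n_rep
        assert surv[~pure].mean() > surv[pure].mean()
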