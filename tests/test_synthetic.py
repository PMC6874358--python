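"""Synthetic-data generator: determinism, range fidelity, planted effects."""

import numpy as np

import pytest
from pandas.testing import assert_frame_equal

from urbanbef.bef import rank_correlation
from urbanbef.synthetic import (
    TABLE_BOUNDS,
    SyntheticScenario,
    make_communities,
    make_isotope_data,
    make_light_curves,
    make_plots,
    make_species_pool,
    simulate_bundle,
)
from urbanbef.isotopes import aggregate_plot


class TestScenarioValidation:
    def test_bad_alien_fraction(self):
        with pytest.raises(ValueError):
            SyntheticScenario(alien_fraction=1.2)

    def test_richness_range_outside_pool(self):
        with pytest.raises(ValueError):
            SyntheticScenario(n_species_pool=20, richness_range=(13, 48))

    def test_negative_noise(self):
        with pytest.raises(ValueError):
            SyntheticScenario(replicate_cv=-0.1)


class TestSpeciesPool:
    def test_zero_alien_fraction_boundary(self):
        cat = make_species_pool(SyntheticScenario(alien_fraction=0.0, seed=1))
        assert (cat.attributes["status"] == "native").all()

    def test_about_one_third_of_forbs_alien(self):
        cat = make_species_pool(SyntheticScenario(
            n_species_pool=600, alien_fraction=0.33, seed=1))
        forbs = cat.attributes[cat.attributes["functional_group"] == "forb"]
        frac = (forbs["status"] == "alien").mean()
        assert frac == pytest.approx(1 / 3, abs=0.07)

    def test_determinism_same_seed(self):
        a = make_species_pool(SyntheticScenario(seed=5))
        b = make_species_pool(SyntheticScenario(seed=5))
        assert_frame_equal(a.attributes, b.attributes)
        assert_frame_equal(a.traits, b.traits)

    def test_c4_rare_and_graminoid_only(self):
        cat = make_species_pool(SyntheticScenario(n_species_pool=400, seed=2))
        c4 = cat.attributes[cat.attributes["pathway"] == "C4"]
        assert len(c4) <= 0.05 * 400
        assert (c4["functional_group"] == "graminoid").all()

    def test_residence_times_split_at_horizon(self):
        scen = SyntheticScenario(seed=3)
        cat = make_species_pool(scen)
        attrs = cat.attributes
        aliens = attrs[attrs["status"] == "alien"]
        natives = attrs[attrs["status"] == "native"]
        assert (aliens["residence_time"] <= scen.horizon).all()
        assert (natives["residence_time"] >= scen.horizon).all()

    def test_trivial_pool_rejected(self):
        with pytest.raises(ValueError):
            make_species_pool(SyntheticScenario(n_species_pool=1,
                                                richness_range=(1, 1)))


class TestPlots:
    def test_range_fidelity_all_columns(self):
        plots = make_plots(SyntheticScenario(n_plots=200, seed=4))
        for col, (lo, hi) in TABLE_BOUNDS.items():
            v = plots[col]
            assert v.min() >= lo - 1e-9, col
            assert v.max() <= hi + 1e-9, col

    def test_single_plot_all_columns_present(self):
        plots = make_plots(SyntheticScenario(n_plots=1, seed=0))
        assert len(plots) == 1
        assert set(TABLE_BOUNDS) <= set(plots.columns)
        assert "age" in plots.columns

    def test_buffer_radii_positively_correlated(self):
        plots = make_plots(SyntheticScenario(n_plots=200, seed=4))
        r = np.corrcoef(plots["impervious_100"], plots["impervious_500"])[0, 1]
        assert r > 0.0
        r2 = np.corrcoef(plots["popd_100"], plots["popd_5000"])[0, 1]
        assert r2 > 0.0


class TestCommunities:
    def test_replicate_count_is_three(self, default_bundle):
        reps = default_bundle["communities"].groupby("plot")["replicate"].nunique()
        assert (reps == 3).all()

    def test_biomass_nonnegative_and_richness_in_range(self, default_bundle,
                                                       default_scenario):
        com = default_bundle["communities"]
        assert (com["biomass_g"] >= 0).all()
        lo, hi = default_scenario.richness_range
        richness = com.groupby("plot")["species"].nunique()
        assert richness.between(lo, hi).all()

    def test_null_richness_effect_gives_flat_slope(self):
        scen = SyntheticScenario(n_plots=100, richness_agb_effect=0.0, seed=6)
        cat = make_species_pool(scen)
        plots = make_plots(scen)
        com = make_communities(cat, plots, scen)
        richness = com.groupby("plot")["species"].nunique()
        agb = (com.groupby(["plot", "replicate"])["biomass_g"].sum()
               .groupby("plot").mean() * 10)
        from scipy.stats import linregress
        res = linregress(richness.loc[agb.index], agb)
        assert res.pvalue > 0.05

    def test_richness_range_exceeding_pool_rejected(self):
        scen = SyntheticScenario(seed=0)
        cat = make_species_pool(SyntheticScenario(n_species_pool=30,
                                                  richness_range=(5, 20), seed=0))
        plots = make_plots(scen)
        with pytest.raises(ValueError, match="pool"):
            make_communities(cat, plots, scen)

    def test_determinism(self):
        scen = SyntheticScenario(seed=9)
        cat = make_species_pool(scen)
        plots = make_plots(scen)
        assert_frame_equal(make_communities(cat, plots, scen),
                           make_communities(cat, plots, scen))


class TestIsotopeData:
    def test_soil_complete_per_plot_and_replicate(self, default_bundle,
                                                  default_scenario):
        soil = default_bundle["soil"]
        counts = soil.groupby("plot")["replicate"].nunique()
        assert (counts == default_scenario.n_replicates).all()
        assert len(counts) == default_scenario.n_plots

    def test_c4_rows_in_distinct_delta13c_window(self):
        scen = SyntheticScenario(seed=21, n_plots=60, c4_fraction=0.05)
        cat = make_species_pool(scen)
        plots = make_plots(scen)
        com = make_communities(cat, plots, scen)
        iso, _ = make_isotope_data(com, plots, scen, cat)
        c4 = iso[iso["c4"]]
        c3 = iso[~iso["c4"]]
        if len(c4):
            assert c4["d13c"].between(-16, -10).all()
        assert (c3["d13c"] < -20).all()

    def test_planted_svf_effect_recovered_by_spearman(self):
        scen = SyntheticScenario(seed=12, n_plots=50)
        b = simulate_bundle(scen)
        prox = aggregate_plot(b["communities"], b["isotopes"], b["soil"],
                              b["catalog"])
        svf = b["plots"]["svf"].reindex(prox.index)
        rho, p, n = rank_correlation(svf, prox["iWUE_C"])
        assert rho > 0
        assert p < 0.05

    def test_zero_urban_effect_mostly_undetected(self):
        # null calibration: with no planted urban link, the urban composite
        # should not correlate with dd15N beyond chance
        detections = 0
        n_runs = 20
        for seed in range(n_runs):
            scen = SyntheticScenario(seed=seed, n_plots=20,
                                     urban_dd15n_effect=0.0)
            b = simulate_bundle(scen)
            prox = aggregate_plot(b["communities"], b["isotopes"], b["soil"],
                                  b["catalog"])
            urb = b["plots"]["impervious_500"].reindex(prox.index)
            _, p, _ = rank_correlation(urb, prox["dd15N_C"])
            detections += p <= 0.05
        assert detections / n_runs <= 0.10

    def test_absent_group_absent_from_isotope_table(self, default_bundle):
        iso = default_bundle["isotopes"]
        com = default_bundle["communities"].copy()
        attrs = default_bundle["catalog"].attributes
        com["group"] = (com["species"].map(attrs["status"]) + "_"
                        + com["species"].map(attrs["functional_group"]))
        present = set(map(tuple, com[["plot", "group"]].drop_duplicates().to_numpy()))
        for plot, group in iso[["plot", "group"]].drop_duplicates().to_numpy():
            assert (plot, group) in present


class TestLightCurves:
    def test_default_levels(self):
        c = make_light_curves(150.0, 0.003)[0]
        assert list(c.ppfd) == [0, 100, 300, 600, 900, 1200, 1500, 2000]

    def test_negative_noise_rejected(self):
        with pytest.raises(ValueError):
            make_light_curves(150.0, 0.003, noise_sd=-1.0)

    def test_few_levels_rejected(self):
        with pytest.raises(ValueError):
            make_light_curves(150.0, 0.003, ppfd_levels=[0, 100, 300])

    def test_yields_within_unit_interval(self):
        for c in make_light_curves(150.0, 0.003, n_individuals=5,
                                   noise_sd=20.0, seed=1):
            assert ((c.yields >= 0) & (c.yields <= 1)).all()

    def test_deterministic_under_seed(self):
        a = make_light_curves(150.0, 0.003, noise_sd=5.0, seed=2)
        b = make_light_curves(150.0, 0.003, noise_sd=5.0, seed=2)
        for ca, cb in zip(a, b):
            assert np.array_equal(ca.yields, cb.yields)


def test_bundle_determinism_bit_identical():
    a = simulate_bundle(SyntheticScenario(seed=33))
    b = simulate_bundle(SyntheticScenario(seed=33))
    assert_frame_equal(a["plots"], b["plots"])
    assert_frame_equal(a["communities"], b["communities"])
    assert_frame_equal(a["isotopes"], b["isotopes"])
    assert_frame_equal(a["soil"], b["soil"])
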