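"""Isotope chain: delta notation, discrimination, iWUE, 15N enrichment,
pool-weighted mixing and the per-plot proxy aggregation."""

import numpy as np
import pandas as pd
import pytest

from urbanbef.isotopes import (
    GROUP_POOLS,
    aggregate_plot,
    carbon_discrimination,
    delta_value,
    iwue,
    n_enrichment,
    pool_weighted_delta,
)
from urbanbef.synthetic import SyntheticScenario, simulate_bundle

from conftest import tiny_catalog


def naive_chain(d13c_plant, d13c_air=-8.0, ca=400.0, a=4.4, b_prime=27.0):
    """Spreadsheet-style oracle for the delta13C -> iWUE chain, written
    step by step and independently of the library implementation."""
    disc = (d13c_air - d13c_plant) / (1.0 + d13c_plant / 1000.0)
    ratio = (b_prime - disc) / (b_prime - a)
    return (ca / 1.6) * ratio


class TestDeltaValue:
    def test_identity(self):
        assert delta_value(0.0112372, 0.0112372) == 0.0

    def test_per_mil_scaling(self):
        assert delta_value(1.001 * 0.0112372, 0.0112372) == pytest.approx(1.0)
        assert delta_value(0.99 * 0.0112372, 0.0112372) == pytest.approx(-10.0)

    def test_nonpositive_reference_rejected(self):
        with pytest.raises(ValueError):
            delta_value(0.01, 0.0)


class TestDiscrimination:
    def test_plant_equal_to_air(self):
        assert carbon_discrimination(-8.0) == pytest.approx(0.0)

    def test_hand_value(self):
        # (-8 - (-28)) / (1 - 0.028) = 20 / 0.972
        assert carbon_discrimination(-28.0) == pytest.approx(20.576, abs=5e-4)

    def test_monotone_decreasing_in_plant_delta(self):
        grid = np.linspace(-35, -20, 50)
        disc = carbon_discrimination(grid)
        assert np.all(np.diff(disc) < 0)

    def test_pole_rejected(self):
        with pytest.raises(ZeroDivisionError):
            carbon_discrimination(-1000.0)


class TestIWUE:
    def test_boundary_identities_exact(self):
        assert iwue(27.0) == 0.0
        assert iwue(4.4) == pytest.approx(250.0, abs=1e-12)

    def test_hand_value(self):
        assert iwue(20.576) == pytest.approx(71.06, abs=5e-3)

    def test_invalid_constants(self):
        with pytest.raises(ValueError):
            iwue(10.0, a=30.0, b_prime=27.0)

    def test_chain_matches_naive_oracle(self):
        rng = np.random.default_rng(42)
        d13c = rng.uniform(-35.0, -20.0, 1000)
        ours = iwue(carbon_discrimination(d13c))
        theirs = np.array([naive_chain(v) for v in d13c])
        assert np.max(np.abs(ours - theirs)) < 1e-9

    def test_chain_increasing_in_plant_delta(self):
        grid = np.linspace(-35, -20, 100)
        vals = iwue(carbon_discrimination(grid))
        assert np.all(np.diff(vals) > 0)


class TestNEnrichment:
    def test_values(self):
        assert n_enrichment(2.0, 2.0) == 0.0
        assert n_enrichment(-1.5, 2.0) == pytest.approx(-3.5)

    def test_antisymmetric(self):
        assert n_enrichment(1.2, 3.4) == -n_enrichment(3.4, 1.2)


class TestPoolWeightedDelta:
    def test_single_sample_identity(self):
        assert pool_weighted_delta([(5.0, -27.3)]) == -27.3

    def test_hand_weighted_mean(self):
        assert pool_weighted_delta([(10, -27.0), (30, -29.0)]) == pytest.approx(-28.5)

    def test_c4_exclusion_leaves_result_unchanged(self):
        base = pool_weighted_delta([(10, -27.0), (30, -29.0)])
        with_c4 = pool_weighted_delta(
            [(10, -27.0), (30, -29.0), (10_000, -12.0)], exclude={2}
        )
        assert with_c4 == base

    def test_all_excluded_rejected(self):
        with pytest.raises(ValueError):
            pool_weighted_delta([(10, -12.0)], exclude={0})

    def test_convex_combination(self):
        rng = np.random.default_rng(1)
        for _ in range(200):
            n = rng.integers(1, 6)
            samples = [(rng.uniform(0.1, 10), rng.uniform(-32, -24)) for _ in range(n)]
            mix = pool_weighted_delta(samples)
            deltas = [d for _, d in samples]
            assert min(deltas) - 1e-12 <= mix <= max(deltas) + 1e-12


def _single_group_tables():
    catalog = tiny_catalog()
    community = pd.DataFrame(
        {
            "plot": ["p1"] * 3,
            "replicate": [1, 2, 3],
            "species": ["f_nat"] * 3,
            "biomass_g": [10.0, 12.0, 8.0],
        }
    )
    isotopes = pd.DataFrame(
        {
            "plot": ["p1"] * 3,
            "replicate": [1, 2, 3],
            "group": ["native_forb"] * 3,
            "c4": [False] * 3,
            "dry_mass_g": [10.0, 12.0, 8.0],
            "c_percent": [45.0] * 3,
            "n_percent": [1.5] * 3,
            "d13c": [-28.0, -27.0, -29.0],
            "d15n": [0.5, 0.2, 0.8],
        }
    )
    soil = pd.DataFrame(
        {"plot": ["p1"] * 3, "replicate": [1, 2, 3], "d15n_soil": [2.0, 2.2, 1.8]}
    )
    return community, isotopes, soil, catalog


class TestAggregatePlot:
    def test_single_group_community_equals_group(self):
        community, isotopes, soil, catalog = _single_group_tables()
        prox = aggregate_plot(community, isotopes, soil, catalog)
        row = prox.loc["p1"]
        assert row["iWUE_C"] == pytest.approx(row["iWUE_NF"])
        assert row["dd15N_C"] == pytest.approx(row["dd15N_NF"])
        # AGB: mean quadrat biomass 10 g on 0.1 m^2 -> 100 g m^-2
        assert row["AGB_C"] == pytest.approx(100.0)

    def test_missing_group_is_nan_not_zero(self):
        community, isotopes, soil, catalog = _single_group_tables()
        prox = aggregate_plot(community, isotopes, soil, catalog)
        assert np.isnan(prox.loc["p1", "iWUE_G"])
        assert prox.loc["p1", "AGB_G"] == 0.0

    def test_missing_soil_sample_raises(self):
        community, isotopes, soil, catalog = _single_group_tables()
        with pytest.raises(ValueError, match="soil"):
            aggregate_plot(community, isotopes, soil.iloc[:0], catalog)

    def test_group_agb_adds_up_and_mixing_is_convex(self, default_bundle):
        b = default_bundle
        prox = aggregate_plot(b["communities"], b["isotopes"], b["soil"], b["catalog"])
        assert np.allclose(prox["AGB_N"] + prox["AGB_A"], prox["AGB_C"])
        assert np.allclose(prox["AGB_G"] + prox["AGB_F"] + prox["AGB_L"],
                           prox["AGB_C"])
        base_cols = [f"iWUE_{s}" for s in ("NG", "NF", "NL", "AG", "AF", "AL")]
        spans = prox[base_cols]
        lo = spans.min(axis=1) - 1e-9
        hi = spans.max(axis=1) + 1e-9
        ok = prox["iWUE_C"].notna()
        assert ((prox.loc[ok, "iWUE_C"] >= lo[ok])
                & (prox.loc[ok, "iWUE_C"] <= hi[ok])).all()

    def test_planted_biomass_level_recovered(self):
        # plateau 350 with 90% saturation at 30 species: plot means should
        # scatter around the planted curve, so the overall mean sits close
        # to the curve's mean over the drawn richness values
        scen = SyntheticScenario(seed=3, n_plots=100)
        b = simulate_bundle(scen)
        prox = aggregate_plot(b["communities"], b["isotopes"], b["soil"], b["catalog"])
        richness = b["communities"].groupby("plot")["species"].nunique()
        k = np.log(10) / scen.agb_sat_richness
        expected = (scen.agb_plateau * (1 - np.exp(-k * richness))).mean()
        assert prox["AGB_C"].mean() == pytest.approx(expected, rel=0.10)

    def test_c4_material_excluded_from_carbon_mixing(self):
        community, isotopes, soil, catalog = _single_group_tables()
        with_c4 = isotopes.copy()
        extra = isotopes.iloc[[0]].assign(c4=True, d13c=-12.0, dry_mass_g=1e4)
        with_c4 = pd.concat([with_c4, extra], ignore_index=True)
        a = aggregate_plot(community, isotopes, soil, catalog)
        b = aggregate_plot(community, with_c4, soil, catalog)
        assert b.loc["p1", "iWUE_C"] == pytest.approx(a.loc["p1", "iWUE_C"])
        # the N side has no exclusion rule, so dd15N does shift
        assert b.loc["p1", "dd15N_C"] != a.loc["p1", "dd15N_C"]

    def test_all_proxy_columns_present(self, default_bundle):
        b = default_bundle
        prox = aggregate_plot(b["communities"], b["isotopes"], b["soil"], b["catalog"])
        for prefix in ("AGB", "iWUE", "dd15N"):
            for suffix in GROUP_POOLS:
                assert f"{prefix}_{suffix}" in prox.columns
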