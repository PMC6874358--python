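"""Synthetic urban-grassland study generator with planted effects.

Emulates a field campaign on dry grassland plots along an urbanization
gradient: a regional species pool with biogeographic status, functional
group, photosynthetic pathway, residence times and a 12-trait table; plot
covariates spanning the observed urban/abiotic ranges, with buffer-radius
variants of each urban parameter tied together by a latent urban-intensity
factor; replicated clip-quadrat community biomass following a saturating
richness -> biomass relation; isotope samples whose delta13C and delta15N
encode planted sky-view-factor, soil-water and urban-intensity effects on
iWUE and the 15N enrichment factor; and fluorescence light curves from a
known rise-to-maximum model. Every planted link has a known coefficient so
each downstream stage has a recoverable ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .diversity import SpeciesCatalog
from .isotopes import QUADRAT_AREA_M2
from .light import ABSORPTANCE, PPFD_LEVELS, PSII_FRACTION, LightCurve

__all__ = [
    "SyntheticScenario",
    "TABLE_BOUNDS",
    "URBAN_FAMILIES",
    "make_species_pool",
    "make_plots",
    "make_communities",
    "make_isotope_data",
    "make_light_curves",
    "simulate_bundle",
]

#: Min-max bounds of the plot covariates (units as in the field campaign).
TABLE_BOUNDS: dict[str, tuple[float, float]] = {
    "size_patch": (335.0, 19058.0),
    "grassland_100": (0.0, 0.28),
    "grassland_500": (0.0, 0.15),
    "grassland_1000": (0.0, 0.11),
    "grassland_5000": (0.0, 0.02),
    "impervious_100": (0.0, 70.3),
    "impervious_500": (1.2, 67.6),
    "impervious_1000": (1.1, 71.2),
    "impervious_5000": (14.1, 63.1),
    "far_100": (0.0, 1.21),
    "far_500": (0.0, 1.1),
    "far_1000": (0.0, 1.28),
    "far_5000": (0.1, 1.1),
    "popd_100": (0.0, 97.1),
    "popd_500": (0.0, 105.3),
    "popd_1000": (0.1, 125.8),
    "popd_5000": (10.2, 106.3),
    "roadd_100": (0.0, 2.2),
    "roadd_500": (0.2, 24.7),
    "roadd_1000": (2.7, 67.6),
    "roadd_5000": (385.7, 1226.4),
    "railwd_100": (0.0, 2.6),
    "railwd_500": (0.0, 8.4),
    "railwd_1000": (0.0, 29.0),
    "railwd_5000": (11.5, 210.5),
    "rdist": (15.0, 496.0),
    "railwdist": (15.0, 4111.0),
    "airt_longterm": (8.0, 10.5),
    "urbclim": (1.0, 4.0),
    "airt": (14.3, 16.7),
    "airrh": (67.0, 88.0),
    "svf": (0.68, 0.99),
    "soil_n": (0.01, 0.60),
    "soil_cu": (0.05, 0.42),
    "soil_zn": (0.03, 10.71),
    "soil_cd": (0.0, 0.08),
    "soil_pb": (0.01, 0.28),
    "soil_ni": (0.0, 0.15),
    "soil_wc": (0.01, 0.29),
    "moss_cover": (0.0, 60.0),
    "litter_cover": (10.0, 80.0),
}

#: Buffer-radius families driven by the shared latent urban-intensity factor.
URBAN_FAMILIES = ("impervious", "far", "popd", "roadd", "railwd")

#: Columns whose 500-m members form the observable urban-intensity composite.
URBAN_COMPOSITE = ("impervious_500", "far_500", "popd_500", "railwd_500")

TRAIT_COLUMNS = (
    "height_m", "sla_mm2_mg", "leaf_area_mm2", "seed_mass_mg",
    "dispersal_length_mm", "leaf_n_mg_g", "life_form", "flower_color",
    "flower_class", "clonal_growth", "n_fixation", "mycorrhiza",
)


@dataclass
class SyntheticScenario:
    """Study conditions and planted effect sizes.

    Sample sizes mirror the field design (20 plots, 3 clip quadrats per
    plot, plot richness 13-48 from a regional pool); effect sizes are the
    planted link coefficients that downstream stages must recover.
    """

    n_plots: int = 20
    n_species_pool: int = 120
    alien_fraction: float = 0.33
    n_replicates: int = 3
    richness_range: tuple[int, int] = (13, 48)
    # planted links
    richness_agb_effect: float = 1.0  # 0 = flat, 1 = full saturating curve
    svf_iwue_effect: float = 30.0  # umol mol^-1 per unit SVF
    soilwater_iwue_effect: float = -20.0  # umol mol^-1 per unit Wc
    urban_dd15n_effect: float = 4.0  # per mil per unit urban composite
    # saturating richness -> community biomass relation (g m^-2)
    agb_plateau: float = 350.0
    agb_sat_richness: float = 30.0  # richness at 90% of the plateau
    agb_base: float = 280.0  # level used when richness_agb_effect = 0
    # noise
    replicate_cv: float = 0.30  # within-plot replicate CV of biomass
    agb_plot_cv: float = 0.12
    iwue_noise_sd: float = 1.5  # umol mol^-1
    dd15n_noise_sd: float = 0.8  # per mil
    # observed community composition levels
    alien_agb_share: float = 0.131
    iwue_base: float = 50.8  # umol mol^-1
    dd15n_base: float = -3.43  # per mil
    horizon: float = 527.0
    trait_missing_rate: float = 0.05
    c4_fraction: float = 0.03
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_plots < 1 or self.n_species_pool < 1 or self.n_replicates < 1:
            raise ValueError("sizes must be positive")
        if not 0.0 <= self.alien_fraction <= 1.0:
            raise ValueError("alien_fraction must lie in [0, 1]")
        lo, hi = self.richness_range
        if not (1 <= lo <= hi <= self.n_species_pool):
            raise ValueError("richness_range must lie within [1, n_species_pool]")
        for name in ("replicate_cv", "agb_plot_cv", "iwue_noise_sd",
                     "dd15n_noise_sd", "trait_missing_rate"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.horizon <= 0:
            raise ValueError("horizon must be > 0")


def _rng(scenario: SyntheticScenario, key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(scenario.seed, spawn_key=(key,)))


def make_species_pool(scenario: SyntheticScenario) -> SpeciesCatalog:
    """Draw the regional species pool with status, groups and traits.

    Aliens (neophytes) occur mostly among forbs at the scenario's
    ``alien_fraction``; alien graminoids/legumes are rare. C4 species are a
    small graminoid minority, capped at 5% of the pool. Aliens' residence
    times are uniform on [0, horizon]; natives sit at/above the horizon.
    """
    if scenario.n_species_pool < 2:
        raise ValueError("need a pool of at least 2 species")
    rng = _rng(scenario, 1)
    n = scenario.n_species_pool
    species = pd.Index([f"sp{k:04d}" for k in range(1, n + 1)], name="species")

    fg = rng.choice(("graminoid", "forb", "legume"), size=n, p=(0.35, 0.50, 0.15))
    af = scenario.alien_fraction
    p_alien = np.where(fg == "forb", af, 0.1 * af)
    alien = rng.random(n) < p_alien
    status = np.where(alien, "alien", "native")

    c4 = (fg == "graminoid") & (rng.random(n) < scenario.c4_fraction)
    cap = int(0.05 * n)
    if c4.sum() > cap:
        keep = rng.choice(np.flatnonzero(c4), size=cap, replace=False)
        c4 = np.zeros(n, dtype=bool)
        c4[keep] = True
    pathway = np.where(c4, "C4", "C3")

    h = scenario.horizon
    residence = np.where(
        alien, rng.uniform(0.0, h, size=n), h + rng.uniform(0.0, h, size=n)
    )

    attributes = pd.DataFrame(
        {
            "status": status,
            "functional_group": fg,
            "pathway": pathway,
            "residence_time": residence,
        },
        index=species,
    )

    traits = pd.DataFrame(
        {
            "height_m": rng.lognormal(-1.0, 0.7, n),
            "sla_mm2_mg": rng.lognormal(3.0, 0.4, n),
            "leaf_area_mm2": rng.lognormal(6.0, 1.0, n),
            "seed_mass_mg": rng.lognormal(0.0, 1.2, n),
            "dispersal_length_mm": rng.lognormal(0.5, 0.8, n),
            "leaf_n_mg_g": np.clip(rng.normal(20.0, 5.0, n), 5.0, None),
            "life_form": rng.choice(
                ("therophyte", "hemicryptophyte", "geophyte", "chamaephyte"),
                size=n, p=(0.25, 0.5, 0.15, 0.1)),
            "flower_color": rng.choice(
                ("white", "yellow", "blue", "red", "green"), size=n),
            "flower_class": rng.choice(
                ("wind", "insect_open", "insect_specialized"), size=n,
                p=(0.4, 0.4, 0.2)),
            "clonal_growth": rng.choice(
                ("none", "rhizome", "stolon", "bulbil"), size=n,
                p=(0.45, 0.3, 0.15, 0.1)),
            "n_fixation": np.where(fg == "legume", "yes", "no"),
            "mycorrhiza": rng.choice(
                ("obligate", "facultative", "none"), size=n, p=(0.3, 0.5, 0.2)),
        },
        index=species,
    )[list(TRAIT_COLUMNS)]

    if scenario.trait_missing_rate > 0:
        for col in ("sla_mm2_mg", "seed_mass_mg", "leaf_n_mg_g"):
            mask = rng.random(n) < scenario.trait_missing_rate
            traits.loc[mask, col] = np.nan

    return SpeciesCatalog(attributes=attributes, traits=traits)


def make_plots(scenario: SyntheticScenario) -> pd.DataFrame:
    """Plot covariate table within the observed min-max bounds.

    A latent urban-intensity factor per plot drives every buffer-radius
    member of the urban families (plus, negatively, grassland share and
    road/railway distances), so buffer variants of one family are
    positively correlated — the collinearity the driver screen must
    disentangle. Remaining covariates are independent uniforms.
    """
    rng = _rng(scenario, 2)
    n = scenario.n_plots
    plots = pd.Index([f"plot{k:02d}" for k in range(1, n + 1)], name="plot")
    u = rng.uniform(0.0, 1.0, n)  # latent urban intensity

    def scaled(base, w, lo, hi):
        q = np.clip(w * base + (1.0 - w) * rng.uniform(0.0, 1.0, n), 0.0, 1.0)
        return lo + (hi - lo) * q

    data: dict[str, np.ndarray] = {}
    for name, (lo, hi) in TABLE_BOUNDS.items():
        fam = name.split("_")[0]
        if fam in URBAN_FAMILIES:
            data[name] = scaled(u, 0.7, lo, hi)
        elif fam == "grassland":
            data[name] = scaled(1.0 - u, 0.7, lo, hi)
        elif name in ("rdist", "railwdist"):
            data[name] = scaled(1.0 - u, 0.5, lo, hi)
        elif name in ("urbclim", "airt_longterm", "airt"):
            data[name] = scaled(u, 0.4, lo, hi)
        else:
            data[name] = rng.uniform(lo, hi, n)
    data["urbclim"] = np.round(data["urbclim"])
    df = pd.DataFrame(data, index=plots)
    df.insert(0, "age", np.where(rng.random(n) < 0.5, "O", "N"))
    return df


def _saturating(richness, scenario: SyntheticScenario) -> np.ndarray:
    k = np.log(10.0) / scenario.agb_sat_richness
    return scenario.agb_plateau * (1.0 - np.exp(-k * np.asarray(richness, float)))


def make_communities(
    catalog: SpeciesCatalog,
    plots: pd.DataFrame,
    scenario: SyntheticScenario,
) -> pd.DataFrame:
    """Replicated clip-quadrat biomass per plot.

    Plot richness is uniform on ``richness_range``; community biomass
    (g m^-2) follows the planted saturating richness relation interpolated
    by ``richness_agb_effect`` plus lognormal plot noise, is split across
    species with aliens pinned near the scenario's alien biomass share, and
    each of the ``n_replicates`` quadrats re-draws the community total with
    the stated replicate CV. Biomass is reported in grams per quadrat.
    """
    if len(catalog) == 0 or len(plots) == 0:
        raise ValueError("catalog and plots must be non-empty")
    lo, hi = scenario.richness_range
    if hi > len(catalog):
        raise ValueError("richness_range exceeds species pool")
    rng = _rng(scenario, 3)
    attrs = catalog.attributes
    species = np.asarray(attrs.index)
    is_alien = (attrs["status"] == "alien").to_numpy()

    sigma_rep = scenario.replicate_cv
    sigma_plot = scenario.agb_plot_cv
    eff = scenario.richness_agb_effect
    rows = []
    for plot in plots.index:
        richness = int(rng.integers(lo, hi + 1))
        chosen = rng.choice(len(species), size=richness, replace=False)
        mu = eff * float(_saturating(richness, scenario)) + (1.0 - eff) * scenario.agb_base
        plot_total = mu * rng.lognormal(-0.5 * sigma_plot**2, sigma_plot)

        alien_idx = chosen[is_alien[chosen]]
        native_idx = chosen[~is_alien[chosen]]
        shares = np.zeros(richness)
        if len(alien_idx) and len(native_idx):
            alien_total = float(np.clip(
                rng.normal(scenario.alien_agb_share, 0.03), 0.01, 0.6))
        elif len(alien_idx):
            alien_total = 1.0
        else:
            alien_total = 0.0
        if len(alien_idx):
            w = rng.dirichlet(np.full(len(alien_idx), 0.8))
            shares[is_alien[chosen]] = w * alien_total
        if len(native_idx):
            w = rng.dirichlet(np.full(len(native_idx), 0.8))
            shares[~is_alien[chosen]] = w * (1.0 - alien_total)

        per_species_gm2 = plot_total * shares
        for rep in range(1, scenario.n_replicates + 1):
            rep_factor = rng.lognormal(-0.5 * sigma_rep**2, sigma_rep)
            jitter = rng.lognormal(-0.5 * 0.15**2, 0.15, richness)
            quadrat = per_species_gm2 * QUADRAT_AREA_M2 * rep_factor * jitter
            for s_idx, biomass in zip(chosen, quadrat):
                rows.append(
                    {"plot": plot, "replicate": rep,
                     "species": species[s_idx], "biomass_g": float(biomass)}
                )
    return pd.DataFrame(rows)


def make_isotope_data(
    communities: pd.DataFrame,
    plots: pd.DataFrame,
    scenario: SyntheticScenario,
    catalog: SpeciesCatalog,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Isotope and soil sample tables with planted iWUE/dd15N drivers.

    Group delta13C is generated backwards through the discrimination chain
    from a target iWUE that responds positively to SVF and negatively to
    soil water with the scenario coefficients; plant delta15N is the plot's
    soil background plus an enrichment responding to the observable
    urban-intensity composite. C4 material gets its own rows flagged
    ``c4`` with delta13C in the distinct C4 window (about -16 to -10).
    """
    rng = _rng(scenario, 4)
    attrs = catalog.attributes
    com = communities.copy()
    com["status"] = com["species"].map(attrs["status"])
    com["fg"] = com["species"].map(attrs["functional_group"])
    com["pathway"] = com["species"].map(attrs["pathway"])
    com["group"] = com["status"] + "_" + com["fg"]

    # observable urban composite and centered drivers
    comp = np.zeros(len(plots))
    for col in URBAN_COMPOSITE:
        v = plots[col].to_numpy(float)
        comp += (v - v.min()) / (v.max() - v.min()) if v.max() > v.min() else 0.0
    comp /= len(URBAN_COMPOSITE)
    urban_c = pd.Series(comp - comp.mean(), index=plots.index)
    svf_c = plots["svf"] - plots["svf"].mean()
    wc_c = plots["soil_wc"] - plots["soil_wc"].mean()

    iwue_offs = {"graminoid": 3.0, "forb": -1.5, "legume": -3.0}
    dd15n_offs = {"graminoid": -1.0, "forb": 0.5, "legume": 1.0}
    npct_mean = {"graminoid": 1.2, "forb": 1.8, "legume": 2.5}

    soil_rows = []
    soil_plot = {}
    for plot in plots.index:
        base = rng.normal(2.0, 1.0)
        soil_plot[plot] = base
        for rep in range(1, scenario.n_replicates + 1):
            soil_rows.append(
                {"plot": plot, "replicate": rep,
                 "d15n_soil": float(base + rng.normal(0.0, 0.2))}
            )
    soil = pd.DataFrame(soil_rows)

    iso_rows = []
    grouped = com.groupby(["plot", "replicate", "group"], sort=True)
    for (plot, rep, group), sub in grouped:
        fg = sub["fg"].iloc[0]
        mass_c3 = float(sub.loc[sub["pathway"] == "C3", "biomass_g"].sum())
        mass_c4 = float(sub.loc[sub["pathway"] == "C4", "biomass_g"].sum())

        d15n = (
            soil_plot[plot]
            + scenario.dd15n_base
            + dd15n_offs[fg]
            + scenario.urban_dd15n_effect * float(urban_c.loc[plot])
            + rng.normal(0.0, scenario.dd15n_noise_sd)
        )
        if mass_c3 > 0:
            iwue_target = (
                scenario.iwue_base
                + iwue_offs[fg]
                + scenario.svf_iwue_effect * float(svf_c.loc[plot])
                + scenario.soilwater_iwue_effect * float(wc_c.loc[plot])
                + rng.normal(0.0, scenario.iwue_noise_sd)
            )
            iwue_target = float(np.clip(iwue_target, 5.0, 240.0))
            # invert the discrimination chain to a leaf delta13C
            disc = 27.0 - iwue_target * 1.6 * (27.0 - 4.4) / 400.0
            d13c = (-8.0 - disc) / (1.0 + disc / 1000.0)
            iso_rows.append(
                {"plot": plot, "replicate": rep, "group": group, "c4": False,
                 "dry_mass_g": mass_c3,
                 "c_percent": float(np.clip(rng.normal(45.0, 2.0), 35.0, 55.0)),
                 "n_percent": float(np.clip(rng.normal(npct_mean[fg], 0.3), 0.3, 6.0)),
                 "d13c": float(d13c), "d15n": float(d15n)}
            )
        if mass_c4 > 0:
            iso_rows.append(
                {"plot": plot, "replicate": rep, "group": group, "c4": True,
                 "dry_mass_g": mass_c4,
                 "c_percent": float(np.clip(rng.normal(45.0, 2.0), 35.0, 55.0)),
                 "n_percent": float(np.clip(rng.normal(npct_mean[fg], 0.3), 0.3, 6.0)),
                 "d13c": float(rng.uniform(-16.0, -10.0)),
                 "d15n": float(d15n + rng.normal(0.0, scenario.dd15n_noise_sd))}
            )
    return pd.DataFrame(iso_rows), soil


def make_light_curves(
    a_true: float,
    b_true: float,
    ppfd_levels: Sequence[float] = PPFD_LEVELS,
    n_individuals: int = 3,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> list[LightCurve]:
    """Fluorescence light curves from a known rise-to-maximum ETR model.

    The true ETR at each light step is a(1 - e^{-bx}); Gaussian noise with
    ``noise_sd`` (on the ETR scale) is added and converted back to the
    effective quantum yield dF/Fm' = ETR / (0.5 * 0.84 * PPFD), truncated
    to [0, 1]. At PPFD 0 the analytic small-x yield limit a*b/0.42 is used.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if a_true <= 0 or b_true <= 0:
        raise ValueError("a_true and b_true must be > 0")
    x = np.asarray(sorted(set(float(v) for v in ppfd_levels)))
    if len(x) < 4:
        raise ValueError("need at least 4 distinct PPFD levels")
    if np.any(x < 0):
        raise ValueError("PPFD levels must be >= 0")
    if n_individuals < 1:
        raise ValueError("n_individuals must be positive")
    rng = np.random.default_rng(seed)
    factor = PSII_FRACTION * ABSORPTANCE
    curves = []
    for i in range(1, n_individuals + 1):
        etr_true = a_true * (1.0 - np.exp(-b_true * x))
        eps = rng.normal(0.0, noise_sd, len(x)) if noise_sd > 0 else np.zeros(len(x))
        yields = np.empty(len(x))
        for k, xv in enumerate(x):
            if xv > 0:
                yields[k] = (etr_true[k] + eps[k]) / (factor * xv)
            else:
                yields[k] = (a_true * b_true + eps[k] * b_true) / factor
        yields = np.clip(yields, 0.0, 1.0)
        curves.append(LightCurve(individual=f"ind{i:02d}", ppfd=x, yields=yields))
    return curves


def simulate_bundle(scenario: SyntheticScenario) -> dict:
    """Generate a complete, mutually consistent input bundle."""
    catalog = make_species_pool(scenario)
    plots = make_plots(scenario)
    communities = make_communities(catalog, plots, scenario)
    isotopes, soil = make_isotope_data(communities, plots, scenario, catalog)
    return {
        "catalog": catalog,
        "plots": plots,
        "communities": communities,
        "isotopes": isotopes,
        "soil": soil,
    }
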