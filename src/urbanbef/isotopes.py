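"""Stable-isotope ecophysiology: the three ecosystem-functioning proxies.

Per-plot aboveground biomass (AGB), intrinsic water-use efficiency (iWUE)
derived from leaf delta13C through discrimination theory, and the 15N
enrichment factor (plant delta15N minus soil delta15N) as an indicator of
N-cycle openness. Group delta values are mass-weighted over replicates and
community values follow a C/N-pool-weighted mixing model; C4 material is
excluded from the carbon side because its delta13C does not reflect
water-use efficiency.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "IsotopeConstants",
    "delta_value",
    "carbon_discrimination",
    "iwue",
    "n_enrichment",
    "pool_weighted_delta",
    "aggregate_plot",
    "BASE_GROUPS",
    "QUADRAT_AREA_M2",
]

log = logging.getLogger(__name__)

#: 20 x 50 cm clip quadrat; grams per quadrat x 10 = g per m^2.
QUADRAT_AREA_M2 = 0.1

#: Finest plant-group resolution: biogeographic status x functional group.
BASE_GROUPS = (
    "native_graminoid",
    "native_forb",
    "native_legume",
    "alien_graminoid",
    "alien_forb",
    "alien_legume",
)

#: Proxy column suffix -> base groups pooled into it ('C' = whole community).
GROUP_POOLS = {
    "C": BASE_GROUPS,
    "N": ("native_graminoid", "native_forb", "native_legume"),
    "A": ("alien_graminoid", "alien_forb", "alien_legume"),
    "G": ("native_graminoid", "alien_graminoid"),
    "F": ("native_forb", "alien_forb"),
    "L": ("native_legume", "alien_legume"),
    "NG": ("native_graminoid",),
    "NF": ("native_forb",),
    "NL": ("native_legume",),
    "AG": ("alien_graminoid",),
    "AF": ("alien_forb",),
    "AL": ("alien_legume",),
}


@dataclass(frozen=True)
class IsotopeConstants:
    """Constants of the delta13C -> iWUE chain.

    delta13c_air : 13C composition of atmospheric CO2 (per mil vs VPDB).
    ca : atmospheric CO2 mole fraction (umol mol^-1).
    a : fractionation during CO2 diffusion through stomata (per mil).
    b_prime : fractionation of Rubisco + PEP carboxylation (per mil).
    """

    delta13c_air: float = -8.0
    ca: float = 400.0
    a: float = 4.4
    b_prime: float = 27.0

    def __post_init__(self) -> None:
        if self.a >= self.b_prime:
            raise ValueError("require a < b_prime")


def delta_value(r_sample: float, r_reference: float) -> float:
    """delta notation in per mil: ((R_sample/R_reference) - 1) * 1000."""
    if np.any(np.asarray(r_reference) <= 0):
        raise ValueError("reference ratio must be > 0")
    return (np.asarray(r_sample) / r_reference - 1.0) * 1000.0


def carbon_discrimination(delta13c_plant, delta13c_air: float = -8.0):
    """Carbon isotope discrimination of plant tissue vs atmospheric CO2.

    Delta13C = (delta_air - delta_plant) / (1 + delta_plant/1000), per mil.
    Meaningful for C3 material only (C4 exclusion is handled upstream).
    """
    d = np.asarray(delta13c_plant, dtype=float)
    denom = 1.0 + d / 1000.0
    if np.any(denom == 0):
        raise ZeroDivisionError("delta13C_plant of -1000 per mil")
    out = (delta13c_air - d) / denom
    return float(out) if out.ndim == 0 else out


def iwue(
    discrimination,
    ca: float = 400.0,
    a: float = 4.4,
    b_prime: float = 27.0,
):
    """Intrinsic water-use efficiency from the linear discrimination model.

    iWUE = (Ca/1.6) * (b' - Delta13C) / (b' - a), in umol mol^-1.
    """
    if a >= b_prime:
        raise ValueError("require a < b_prime")
    d = np.asarray(discrimination, dtype=float)
    out = (ca / 1.6) * (b_prime - d) / (b_prime - a)
    return float(out) if out.ndim == 0 else out


def n_enrichment(delta15n_plant, delta15n_soil):
    """15N enrichment factor: plant delta15N minus soil delta15N (per mil).

    Higher values indicate a more open N cycle with larger N losses.
    """
    out = np.asarray(delta15n_plant, dtype=float) - np.asarray(delta15n_soil, float)
    return float(out) if out.ndim == 0 else out


def pool_weighted_delta(
    samples: Sequence[tuple],
    exclude: Iterable[int] | None = None,
) -> float:
    """Mass-weighted mean delta over (pool_mass, delta) samples.

    ``exclude`` holds indices to drop (the C4 rule for carbon pools). Raises
    if everything is excluded or the remaining pool mass is zero.
    """
    drop = set(exclude) if exclude is not None else set()
    masses, deltas = [], []
    for k, (m, d) in enumerate(samples):
        if k in drop:
            continue
        if m < 0:
            raise ValueError("pool mass must be >= 0")
        masses.append(float(m))
        deltas.append(float(d))
    total = sum(masses)
    if not masses or total <= 0:
        raise ValueError("undefined aggregate: no non-excluded mass")
    if len(masses) == 1:  # identity mixing, exact
        return deltas[0]
    return float(np.dot(masses, deltas) / total)


def _weighted_or_nan(mass: np.ndarray, delta: np.ndarray) -> float:
    ok = np.isfinite(mass) & np.isfinite(delta) & (mass > 0)
    if not ok.any():
        return float("nan")
    return float(np.average(delta[ok], weights=mass[ok]))


def aggregate_plot(
    community: pd.DataFrame,
    isotopes: pd.DataFrame,
    soil: pd.DataFrame,
    catalog,
    constants: IsotopeConstants = IsotopeConstants(),
    quadrat_area_m2: float = QUADRAT_AREA_M2,
    soil_statistic: str = "mean",
) -> pd.DataFrame:
    """Derive the per-plot function-proxy table.

    Parameters
    ----------
    community : long format (plot, replicate, species, biomass_g), biomass
        in grams per clip quadrat.
    isotopes : long format (plot, replicate, group, c4, dry_mass_g,
        c_percent, n_percent, d13c, d15n) at the status x functional group
        resolution; rows flagged ``c4`` carry C4 material.
    soil : (plot, replicate, d15n_soil).
    catalog : SpeciesCatalog mapping species to status/functional group.
    soil_statistic : per-plot soil delta15N background, 'mean' (default)
        or 'median' over the replicate soil cores.

    Returns
    -------
    DataFrame indexed by plot with columns AGB_, iWUE_ and dd15N_ for the
    community (C), status classes (N, A), functional groups (G, F, L) and
    their combinations (NG ... AL). Groups present in the community but
    missing from the isotope table yield NaN proxies (logged), never zeros.

    Notes
    -----
    AGB is the mean over replicates of summed quadrat biomass converted to
    g m^-2. Group deltas are C-/N-mass-weighted over replicates; community
    deltas are pool-weighted over groups (mixing model), with C4 rows
    excluded from every C-weighted average. Community values are therefore
    convex combinations of group values.
    """
    attrs = catalog.attributes
    com = community.copy()
    com["status"] = com["species"].map(attrs["status"])
    com["functional_group"] = com["species"].map(attrs["functional_group"])
    if com["status"].isna().any():
        bad = com.loc[com["status"].isna(), "species"].unique()
        raise KeyError(f"species not in catalog: {list(bad)[:5]}")
    com["group"] = com["status"] + "_" + com["functional_group"]

    iso = isotopes.copy()
    if "c4" not in iso.columns:
        iso["c4"] = False
    iso["c_mass"] = iso["dry_mass_g"] * iso["c_percent"] / 100.0
    iso["n_mass"] = iso["dry_mass_g"] * iso["n_percent"] / 100.0

    if soil_statistic not in ("mean", "median"):
        raise ValueError("soil_statistic must be 'mean' or 'median'")
    soil_by_plot = soil.groupby("plot")["d15n_soil"].agg(soil_statistic)

    area = 1.0 / quadrat_area_m2
    rows = []
    for plot, cgrp in com.groupby("plot", sort=True):
        if plot not in soil_by_plot.index:
            raise ValueError(f"plot {plot!r} has no soil sample")
        d15n_soil = float(soil_by_plot.loc[plot])

        # AGB: per replicate sum per group, then replicate mean, then g m^-2
        rep_group = (
            cgrp.groupby(["replicate", "group"])["biomass_g"].sum().unstack(fill_value=0.0)
        )
        agb_base = rep_group.mean(axis=0) * area  # g m^-2 per base group

        igrp = iso[iso["plot"] == plot]
        # group-level deltas: mass-weighted over replicates
        d13c_g, d15n_g, cmass_g, nmass_g = {}, {}, {}, {}
        for g in BASE_GROUPS:
            sub = igrp[igrp["group"] == g]
            if agb_base.get(g, 0.0) > 0 and sub.empty:
                log.warning("plot %r: group %s in community but not in isotope table", plot, g)
            sub_c3 = sub[~sub["c4"]]
            d13c_g[g] = _weighted_or_nan(
                sub_c3["c_mass"].to_numpy(float), sub_c3["d13c"].to_numpy(float)
            )
            d15n_g[g] = _weighted_or_nan(
                sub["n_mass"].to_numpy(float), sub["d15n"].to_numpy(float)
            )
            cmass_g[g] = float(sub_c3["c_mass"].sum())
            nmass_g[g] = float(sub["n_mass"].sum())

        row: dict = {"plot": plot}
        for suffix, members in GROUP_POOLS.items():
            agb = float(sum(agb_base.get(g, 0.0) for g in members))
            row[f"AGB_{suffix}"] = agb
            cm = np.array([cmass_g[g] for g in members])
            nm = np.array([nmass_g[g] for g in members])
            d13 = np.array([d13c_g[g] for g in members])
            d15 = np.array([d15n_g[g] for g in members])
            d13c_mix = _weighted_or_nan(cm, d13)
            d15n_mix = _weighted_or_nan(nm, d15)
            if np.isfinite(d13c_mix):
                disc = carbon_discrimination(d13c_mix, constants.delta13c_air)
                row[f"iWUE_{suffix}"] = iwue(
                    disc, constants.ca, constants.a, constants.b_prime
                )
            else:
                row[f"iWUE_{suffix}"] = float("nan")
            row[f"dd15N_{suffix}"] = (
                n_enrichment(d15n_mix, d15n_soil) if np.isfinite(d15n_mix) else float("nan")
            )
        rows.append(row)
    return pd.DataFrame(rows).set_index("plot")
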