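"""Taxonomic and functional diversity of grassland communities.

Species richness, the proportion of alien (post-1492, neophyte) species,
Rao's quadratic entropy on Gower trait distances, and a temporally weighted
biotic novelty index (BNI) that down-weights trait distances between species
pairs that have coexisted regionally for a long time.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "DEFAULT_HORIZON",
    "SpeciesCatalog",
    "classify_status",
    "gower_distance",
    "rao_q",
    "linear_decay_weight",
    "coexistence_weight",
    "bni",
    "proportion_alien",
    "abundance_from_biomass",
    "plot_diversity_table",
]

#: Default familiarity horizon in years: 1492 (the neophyte cut-off) to 2019.
DEFAULT_HORIZON = 527.0

STATUSES = ("native", "alien")
FUNCTIONAL_GROUPS = ("graminoid", "forb", "legume")
PATHWAYS = ("C3", "C4")

N_TRAITS = 12


class GowerError(ValueError):
    """A species pair shares no co-observed trait."""


@dataclass
class SpeciesCatalog:
    """Per-species attributes plus a mixed-type trait table.

    Parameters
    ----------
    attributes : DataFrame indexed by species id with columns
        ``status`` ('native'/'alien'), ``functional_group``
        ('graminoid'/'forb'/'legume'), ``pathway`` ('C3'/'C4') and
        ``residence_time`` (years since regional arrival, >= 0).
    traits : DataFrame indexed by species id with exactly 12 columns,
        numeric or categorical; NaN marks a missing trait value.
    """

    attributes: pd.DataFrame
    traits: pd.DataFrame

    def __post_init__(self) -> None:
        attrs = self.attributes
        if attrs.index.has_duplicates:
            raise ValueError("duplicate species ids in catalog")
        required = {"status", "functional_group", "pathway", "residence_time"}
        missing = required - set(attrs.columns)
        if missing:
            raise ValueError(f"catalog missing columns: {sorted(missing)}")
        bad = set(attrs["status"]) - set(STATUSES)
        if bad:
            raise ValueError(f"unknown status values: {sorted(bad)}")
        rt = attrs["residence_time"].to_numpy(dtype=float)
        if not np.all(np.isfinite(rt)) or np.any(rt < 0):
            raise ValueError("residence_time must be finite and >= 0")
        if len(self.traits.columns) != N_TRAITS:
            raise ValueError(
                f"trait table must have exactly {N_TRAITS} columns, "
                f"got {len(self.traits.columns)}"
            )
        if not self.traits.index.equals(attrs.index):
            self.traits = self.traits.reindex(attrs.index)

    @property
    def species(self) -> pd.Index:
        return self.attributes.index

    def __len__(self) -> int:
        return len(self.attributes)


def classify_status(value) -> str:
    """Map an introduction year or floristic-status class to native/alien.

    Neophytes — species introduced after 1492 — are 'alien'; archeophytes
    (introduced before 1492) and natives are merged into 'native'.
    """
    if isinstance(value, str):
        token = value.strip().lower()
        if token == "neophyte":
            return "alien"
        if token in ("archeophyte", "native"):
            return "native"
        raise ValueError(f"unknown status class: {value!r}")
    year = float(value)
    return "alien" if year > 1492 else "native"


def _trait_frame(catalog) -> pd.DataFrame:
    if isinstance(catalog, SpeciesCatalog):
        return catalog.traits
    if isinstance(catalog, pd.DataFrame):
        return catalog
    raise TypeError("expected SpeciesCatalog or trait DataFrame")


def gower_distance(catalog) -> pd.DataFrame:
    """Gower distance matrix on a mixed numeric/categorical trait table.

    Numeric traits contribute |x_i - x_j| / range (0 if the trait has zero
    range), categorical traits contribute a 0/1 mismatch, and each pair's
    distance is the mean over traits observed for both species (pairwise
    deletion of missing values).

    Raises
    ------
    GowerError
        If some species pair has no co-observed trait, naming the pair.
    """
    traits = _trait_frame(catalog)
    n = len(traits)
    if n < 2:
        raise ValueError("need at least 2 species")
    total = np.zeros((n, n))
    count = np.zeros((n, n))
    for col in traits.columns:
        s = traits[col]
        if pd.api.types.is_numeric_dtype(s):
            x = s.to_numpy(dtype=float)
            obs = np.isfinite(x)
            rng = np.nanmax(x) - np.nanmin(x) if obs.any() else 0.0
            diff = np.abs(x[:, None] - x[None, :])
            d = diff / rng if rng > 0 else np.zeros((n, n))
        else:
            x = s.to_numpy(dtype=object)
            obs = pd.notna(s).to_numpy()
            d = (x[:, None] != x[None, :]).astype(float)
        valid = obs[:, None] & obs[None, :]
        total[valid] += d[valid]
        count[valid] += 1.0
    if np.any(count == 0):
        i, j = np.argwhere(count == 0)[0]
        raise GowerError(
            f"species pair ({traits.index[i]!r}, {traits.index[j]!r}) "
            "shares no co-observed trait"
        )
    D = total / count
    np.fill_diagonal(D, 0.0)
    D = (D + D.T) / 2.0  # enforce exact symmetry
    return pd.DataFrame(D, index=traits.index, columns=traits.index)


def _as_matrix(D) -> np.ndarray:
    M = D.to_numpy(dtype=float) if isinstance(D, pd.DataFrame) else np.asarray(D, float)
    if M.ndim != 2 or M.shape[0] != M.shape[1]:
        raise ValueError("distance matrix must be square")
    return M


def _as_abundance(p, n: int) -> np.ndarray:
    v = np.asarray(p, dtype=float).ravel()
    if len(v) != n:
        raise ValueError(f"abundance length {len(v)} != matrix size {n}")
    if np.any(v < 0):
        raise ValueError("abundances must be non-negative")
    s = v.sum()
    if not np.isclose(s, 1.0, atol=1e-9):
        raise ValueError(f"abundances must sum to 1 (got {s})")
    return v


def rao_q(p, D) -> float:
    """Rao's quadratic entropy: sum_ij p_i p_j d_ij."""
    M = _as_matrix(D)
    v = _as_abundance(p, M.shape[0])
    return float(v @ M @ v)


def linear_decay_weight(t_min, horizon: float) -> np.ndarray:
    """Default coexistence weight: 1 - min(t, horizon)/horizon."""
    t = np.asarray(t_min, dtype=float)
    return 1.0 - np.minimum(t, horizon) / horizon


def coexistence_weight(
    t_i: float,
    t_j: float,
    horizon: float = DEFAULT_HORIZON,
    strategy: Callable[[np.ndarray, float], np.ndarray] = linear_decay_weight,
) -> float:
    """Temporal coexistence weight for a species pair.

    The pair's shared regional residence is the minimum of the two species'
    residence times; the weight decays from 1 (one species just arrived) to
    0 (both resident for at least ``horizon`` years). The decay form is a
    pluggable strategy; the default is linear.
    """
    if horizon <= 0:
        raise ValueError("horizon must be > 0")
    if t_i < 0 or t_j < 0:
        raise ValueError("residence times must be >= 0")
    w = float(strategy(np.minimum(t_i, t_j), horizon))
    return min(max(w, 0.0), 1.0)


def bni(
    p,
    D,
    residences,
    horizon: float = DEFAULT_HORIZON,
    strategy: Callable[[np.ndarray, float], np.ndarray] = linear_decay_weight,
) -> float:
    """Biotic novelty index: sum_ij p_i p_j d_ij c_ij.

    Rao's Q with each pairwise trait distance additionally weighted by the
    coexistence weight ``c_ij`` of the pair. Always in [0, rao_q(p, D)]:
    novelty can only discount, never add, functional diversity.
    """
    if horizon <= 0:
        raise ValueError("horizon must be > 0")
    M = _as_matrix(D)
    v = _as_abundance(p, M.shape[0])
    t = np.asarray(residences, dtype=float).ravel()
    if len(t) != len(v):
        raise ValueError("residences length mismatch")
    if np.any(t < 0):
        raise ValueError("residence times must be >= 0")
    t_min = np.minimum(t[:, None], t[None, :])
    C = np.clip(strategy(t_min, horizon), 0.0, 1.0)
    return float(v @ (M * C) @ v)


def proportion_alien(catalog: SpeciesCatalog, present_species: Iterable) -> float:
    """Share of alien species among those present at a plot."""
    present = list(present_species)
    if not present:
        raise ValueError("present_species is empty")
    status = catalog.attributes["status"]
    unknown = [s for s in present if s not in status.index]
    if unknown:
        raise KeyError(f"species not in catalog: {unknown[:5]}")
    n_alien = int((status.loc[present] == "alien").sum())
    return n_alien / len(present)


def abundance_from_biomass(biomass: Mapping | pd.Series) -> pd.Series:
    """Relative abundances from biomass (e.g. mean replicate AGB) per species."""
    s = pd.Series(biomass, dtype=float)
    if (s < 0).any():
        raise ValueError("biomass must be non-negative")
    tot = s.sum()
    if tot <= 0:
        raise ValueError("total biomass must be positive")
    return s / tot


def plot_diversity_table(
    community: pd.DataFrame,
    catalog: SpeciesCatalog,
    horizon: float = DEFAULT_HORIZON,
    strategy: Callable[[np.ndarray, float], np.ndarray] = linear_decay_weight,
) -> pd.DataFrame:
    """Per-plot richness, alien proportion, Rao's Q and BNI.

    ``community`` is long-format with columns plot, replicate, species,
    biomass_g. Abundance weights are biomass shares of the plot's mean
    replicate biomass per species.
    """
    D_full = gower_distance(catalog)
    residence = catalog.attributes["residence_time"]
    rows = []
    for plot, grp in community.groupby("plot", sort=True):
        mean_biomass = (
            grp.groupby(["replicate", "species"])["biomass_g"]
            .sum()
            .groupby("species")
            .mean()
        )
        mean_biomass = mean_biomass[mean_biomass > 0]
        sp = mean_biomass.index.tolist()
        richness = len(sp)
        prop_alien = proportion_alien(catalog, sp)
        if richness >= 2:
            p = abundance_from_biomass(mean_biomass).to_numpy()
            D = D_full.loc[sp, sp]
            q = rao_q(p, D)
            nov = bni(p, D, residence.loc[sp].to_numpy(), horizon, strategy)
        else:
            q = 0.0
            nov = 0.0
        rows.append(
            {
                "plot": plot,
                "richness": richness,
                "prop_alien": prop_alien,
                "rao_q": q,
                "bni": nov,
            }
        )
    return pd.DataFrame(rows).set_index("plot")
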