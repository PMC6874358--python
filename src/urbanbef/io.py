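"""Readers, writers, schema validation and run configuration.

All tables are UTF-8, comma-delimited CSV with '.' decimals; units live in
docs/data_dictionary.md, not in headers.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .diversity import SpeciesCatalog
from .synthetic import TRAIT_COLUMNS

__all__ = ["ValidationError", "RunConfig", "Bundle", "read_bundle", "write_bundle"]

SCHEMAS = {
    "species.csv": ["species", "status", "functional_group", "pathway",
                    "residence_time"],
    "traits.csv": ["species", *TRAIT_COLUMNS],
    "plots.csv": ["plot"],
    "communities.csv": ["plot", "replicate", "species", "biomass_g"],
    "isotopes.csv": ["plot", "replicate", "group", "c4", "dry_mass_g",
                     "c_percent", "n_percent", "d13c", "d15n"],
    "soil.csv": ["plot", "replicate", "d15n_soil"],
}


class ValidationError(ValueError):
    """Schema or referential-integrity failure, naming file/column/row."""

    def __init__(self, file: str, message: str, column: str | None = None,
                 row=None):
        loc = file
        if column is not None:
            loc += f", column {column!r}"
        if row is not None:
            loc += f", row {row}"
        super().__init__(f"{loc}: {message}")
        self.file = file
        self.column = column
        self.row = row


@dataclass
class ConstantsBlock:
    """Physical constants of the isotope and fluorescence chains."""

    delta13c_air: float = -8.0
    ca: float = 400.0
    a: float = 4.4
    b_prime: float = 27.0
    psii_fraction: float = 0.5
    absorptance: float = 0.84


@dataclass
class RunConfig:
    """End-to-end run configuration.

    ``input_dir`` of None simulates a bundle from ``scenario`` overrides.
    ``screen`` holds driver-screen settings; the defaults here are desk
    settings (100 trees, 5 importance repeats, 99 permutations) — the
    full-fidelity protocol (2000/100/999) is reached by overriding them.
    ``responses`` selects which proxy columns are screened: 'community',
    'status', 'functional', 'combined' or an explicit list of columns.
    """

    input_dir: str | None = None
    outdir: str = "results"
    seed: int = 0
    scenario: dict = field(default_factory=dict)
    constants: ConstantsBlock = field(default_factory=ConstantsBlock)
    screen: dict = field(default_factory=lambda: {
        "n_trees": 100, "n_importance_repeats": 5, "n_permutations": 99,
        "alpha": 0.05, "cv_folds": 5,
    })
    responses: str | list = "community"
    min_group_presence: float = 0.3
    light_curves: str | None = None
    slopes: str | None = None
    bef_form: str = "saturating"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        consts = raw.pop("constants", {})
        cfg = cls(**raw)
        cfg.constants = ConstantsBlock(**consts) if isinstance(consts, dict) else consts
        return cfg

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


@dataclass
class Bundle:
    """Validated in-memory dataset."""

    catalog: SpeciesCatalog
    plots: pd.DataFrame
    communities: pd.DataFrame
    isotopes: pd.DataFrame
    soil: pd.DataFrame


def _read_csv(path: Path, name: str) -> pd.DataFrame:
    if not path.exists():
        raise ValidationError(name, "file not found")
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise ValidationError(name, "file is empty") from None
    missing = [c for c in SCHEMAS[name] if c not in df.columns]
    if missing:
        raise ValidationError(name, f"missing required column(s) {missing}",
                              column=missing[0])
    if len(df) == 0:
        raise ValidationError(name, "no data rows")
    return df


def read_bundle(input_dir) -> Bundle:
    """Read and validate a complete input bundle from a directory.

    Checks schemas and cross-referential integrity: every community species
    exists in the catalog, every isotope/soil/community plot exists in the
    covariate table.
    """
    root = Path(input_dir)
    species = _read_csv(root / "species.csv", "species.csv")
    traits = _read_csv(root / "traits.csv", "traits.csv")
    plots = _read_csv(root / "plots.csv", "plots.csv")
    communities = _read_csv(root / "communities.csv", "communities.csv")
    isotopes = _read_csv(root / "isotopes.csv", "isotopes.csv")
    soil = _read_csv(root / "soil.csv", "soil.csv")

    try:
        catalog = SpeciesCatalog(
            attributes=species.set_index("species"),
            traits=traits.set_index("species")[list(TRAIT_COLUMNS)],
        )
    except ValueError as err:
        raise ValidationError("species.csv", str(err)) from err

    known = set(catalog.species)
    orphan = communities.loc[~communities["species"].isin(known), "species"]
    if len(orphan):
        row = orphan.index[0]
        raise ValidationError(
            "communities.csv",
            f"unknown species id {orphan.iloc[0]!r} not in species.csv",
            column="species", row=int(row),
        )
    plot_ids = set(plots["plot"])
    for name, df in (("communities.csv", communities),
                     ("isotopes.csv", isotopes), ("soil.csv", soil)):
        bad = df.loc[~df["plot"].isin(plot_ids), "plot"]
        if len(bad):
            raise ValidationError(
                name, f"unknown plot id {bad.iloc[0]!r} not in plots.csv",
                column="plot", row=int(bad.index[0]),
            )
    if (communities["biomass_g"] < 0).any():
        row = communities.index[communities["biomass_g"] < 0][0]
        raise ValidationError("communities.csv", "negative biomass",
                              column="biomass_g", row=int(row))
    iso = isotopes.copy()
    iso["c4"] = iso["c4"].astype(bool)
    return Bundle(catalog=catalog, plots=plots.set_index("plot"),
                  communities=communities, isotopes=iso, soil=soil)


def write_bundle(bundle, outdir) -> None:
    """Write a bundle (or a simulate_bundle dict) as the six input CSVs."""
    root = Path(outdir)
    root.mkdir(parents=True, exist_ok=True)
    if isinstance(bundle, dict):
        catalog = bundle["catalog"]
        plots = bundle["plots"]
        communities = bundle["communities"]
        isotopes = bundle["isotopes"]
        soil = bundle["soil"]
    else:
        catalog, plots = bundle.catalog, bundle.plots
        communities, isotopes, soil = bundle.communities, bundle.isotopes, bundle.soil
    catalog.attributes.reset_index().to_csv(root / "species.csv", index=False)
    catalog.traits.reset_index().to_csv(root / "traits.csv", index=False)
    p = plots.reset_index() if plots.index.name == "plot" else plots
    p.to_csv(root / "plots.csv", index=False)
    communities.to_csv(root / "communities.csv", index=False)
    isotopes.to_csv(root / "isotopes.csv", index=False)
    soil.to_csv(root / "soil.csv", index=False)
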