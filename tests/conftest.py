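import numpy as np
import pandas as pd
import pytest

from urbanbef.diversity import SpeciesCatalog
from urbanbef.synthetic import SyntheticScenario, simulate_bundle


def random_trait_table(rng, n_species, n_numeric=7, n_categorical=5,
                       missing_rate=0.0) -> pd.DataFrame:
    """Mixed trait table helper for property tests (12 columns total)."""
    idx = pd.Index([f"s{k}" for k in range(n_species)], name="species")
    data = {}
    for j in range(n_numeric):
        data[f"num{j}"] = rng.normal(size=n_species) * rng.uniform(0.5, 20)
    for j in range(n_categorical):
        data[f"cat{j}"] = rng.choice(list("abcd"), size=n_species)
    df = pd.DataFrame(data, index=idx)
    if missing_rate > 0:
        for col in df.columns[: n_numeric]:
            mask = rng.random(n_species) < missing_rate
            df.loc[mask, col] = np.nan
    return df


def tiny_catalog() -> SpeciesCatalog:
    """Four-species catalog with known statuses and residence times."""
    idx = pd.Index(["g_nat", "f_nat", "f_ali", "l_nat"], name="species")
    attributes = pd.DataFrame(
        {
            "status": ["native", "native", "alien", "native"],
            "functional_group": ["graminoid", "forb", "forb", "legume"],
            "pathway": ["C3", "C3", "C3", "C3"],
            "residence_time": [600.0, 600.0, 50.0, 600.0],
        },
        index=idx,
    )
    rng = np.random.default_rng(7)
    traits = random_trait_table(rng, 4)
    traits.index = idx
    return SpeciesCatalog(attributes=attributes, traits=traits)


@pytest.fixture(scope="session")
def default_bundle():
    """One shared synthetic study at the default conditions."""
    return simulate_bundle(SyntheticScenario(seed=11))


@pytest.fixture(scope="session")
def default_scenario():
    return SyntheticScenario(seed=11)
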