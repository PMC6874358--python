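# urbanbef

Biodiversity, ecological novelty and ecosystem functioning of grassland
plot networks.

`urbanbef` is for ecologists analysing plot-based grassland campaigns along
urbanization (or other environmental) gradients: replicated clip-quadrat
biomass, species lists with biogeographic status and traits, leaf/soil
stable-isotope measurements, chlorophyll-fluorescence light curves, and a
large table of mutually correlated plot covariates. It answers the
question such campaigns ask: *what drives biomass production, plant water
use and nitrogen cycling across the plots — biodiversity, abiotic
conditions, or the novelty introduced by alien species?*

## What it computes

**Diversity and biotic novelty.** Species richness; the alien (neophyte,
post-1492) proportion; Rao's quadratic entropy
`Q = Σᵢⱼ pᵢ pⱼ dᵢⱼ` on Gower distances over mixed numeric/categorical
traits; and a biotic novelty index
`BNI = Σᵢⱼ pᵢ pⱼ dᵢⱼ cᵢⱼ` that re-weights each pair's trait distance by
how briefly the pair has coexisted regionally,
`cᵢⱼ = 1 − min(tᵢ, tⱼ, H)/H` with familiarity horizon `H` (default 527 y),
so `0 ≤ BNI ≤ Q`.

**Function proxies.** Per plot and plant group: aboveground biomass
(g m⁻²) from replicate quadrats; intrinsic water-use efficiency from leaf
δ¹³C via `Δ¹³C = (δ_air − δ_plant)/(1 + δ_plant/1000)` and
`iWUE = (Ca/1.6)(b′ − Δ¹³C)/(b′ − a)`; and the ¹⁵N enrichment factor
`Δδ¹⁵N = δ¹⁵N_plant − δ¹⁵N_soil` (N-cycle openness). Community values mix
group values weighted by their C and N pools; C4 material is excluded from
the carbon side.

**Leaf ecophysiology.** `Fv/Fm`, `ΔF/Fm′`, `A/E`,
`ETR = 0.5·0.84·ΔF/Fm′·PPFD`, and nonlinear light-response fits
`ETR = a(1 − e^(−b·PPFD))` with cardinal points `ETRmax = a` and
`PPFDsat = ln(10)/b`.

**Driver screen.** A random-forest regressor per proxy with permutation
importance averaged over 100 seed-varied repeats, permutation significance
(999 response permutations, `p = (1+#{null ≥ obs})/(n+1)`, α = 0.05),
zeroing of non-significant predictors, R²-contribution shares,
buffer-radius family sums, and min-max-normalized partial-dependence
curves.

**BEF statistics.** Richness–function regressions (linear, log-linear,
saturating `V(1 − e^(−kS))`), slopes on min-max normalized axes,
range-inclusion synthesis against slope collections from other studies,
rank-based group tests and Spearman correlations.

A synthetic-study generator (`urbanbef.synthetic`) reproduces the whole
input bundle with planted, recoverable effects and is the basis of the
test suite; see `docs/methods.md` for the model and
`docs/data_dictionary.md` for all file schemas.

## Worked example

```python
import numpy as np
from urbanbef import (SyntheticScenario, simulate_bundle, aggregate_plot,
                      bef_regression, DriverScreen)
from urbanbef.diversity import plot_diversity_table
from urbanbef.pipeline import build_predictor_table

scen = SyntheticScenario(seed=42)        # 20 plots, 3 replicates, pool of 120
b = simulate_bundle(scen)
div = plot_diversity_table(b["communities"], b["catalog"])
prox = aggregate_plot(b["communities"], b["isotopes"], b["soil"], b["catalog"])

print(f"mean community AGB : {prox['AGB_C'].mean():.1f} g m-2")
print(f"alien AGB share    : {prox['AGB_A'].sum()/prox['AGB_C'].sum()*100:.1f} %")
print(f"mean community iWUE: {prox['iWUE_C'].mean():.2f} umol mol-1")
print(f"mean dd15N         : {prox['dd15N_C'].mean():.2f} permil")

res = bef_regression(div["richness"], prox["AGB_C"], form="saturating")
print(f"fitted AGB plateau : {res.plateau:.0f} g m-2 "
      f"(90% at {res.saturation_richness:.1f} species)")

X = build_predictor_table(b["plots"], div)
screen = DriverScreen(n_trees=100, n_importance_repeats=5,
                      n_permutations=99, random_state=0)
screen.fit(X, prox["iWUE_C"].to_numpy())
top = screen.result_frame().query("significant").nlargest(3, "r2_contribution_pct")
print(top[["predictor", "p_value", "r2_contribution_pct"]].to_string(index=False))
```

prints

```
mean community AGB : 321.9 g m-2
alien AGB share    : 12.7 %
mean community iWUE: 50.74 umol mol-1
mean dd15N         : -3.29 permil
fitted AGB plateau : 339 g m-2 (90% at 21.3 species)
predictor  p_value  r2_contribution_pct
      svf     0.01             91.81233
```

Reading: on this 20-plot synthetic study aliens carry ~13% of community
biomass, community iWUE sits near 50.7 μmol mol⁻¹ and the N cycle is
moderately closed (Δδ¹⁵N ≈ −3.3 ‰). The richness–biomass relation
saturates around 340 g m⁻², and the driver screen correctly singles out
sky view factor — the planted driver — as the dominant significant
predictor of community iWUE, with all other covariates zeroed out.

The same chain is available from the shell:

```bash
urbanbef simulate --outdir inputs --seed 42
urbanbef proxies --input-dir inputs --out proxies.csv
urbanbef run --outdir results --seed 42        # full pipeline + manifest
```

`DriverScreen`, `LightResponseRegression` and `BEFRegression` are
scikit-learn estimators (`get_params`/`set_params`, fitted attributes with
trailing underscores) and compose with sklearn model selection.

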