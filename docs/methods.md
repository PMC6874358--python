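# Methods

`urbanbef` reimplements, as a tested pipeline, the computational chain of a
biodiversity–ecosystem-functioning field analysis on urban dry-grassland
plots: community diversity and biotic novelty, stable-isotope-derived
function proxies, fluorescence light-response ecophysiology, and a
significance-filtered random-forest screen of the environmental drivers.
This note documents the models, the tunable parameters, the synthetic study
generator, and the numerical and design choices.

## Diversity and biotic novelty

**Status rule.** Species introduced to the region after 1492 (neophytes)
are classed `alien`; archeophytes and natives are merged into `native`.
`classify_status` accepts either an introduction year or a floristic-status
token.

**Gower distance.** Functional distances are computed on a mixed 12-trait
table: numeric traits contribute `|x_i − x_j| / range`, categorical traits
a 0/1 mismatch, averaged over the traits observed for both species
(pairwise deletion). A zero-range numeric trait contributes 0 but still
counts as observed. A species pair with no co-observed trait is an error
naming the pair — we do not impute traits. No installed package provides
mixed-type Gower, so it is implemented here and property-tested against a
naive per-pair evaluation.

**Rao's quadratic entropy.** `rao_q(p, D) = Σᵢⱼ pᵢ pⱼ dᵢⱼ` with abundance
weights `p` and the Gower matrix `D`. Abundances are relative biomass
shares of the plot's mean replicate biomass; presence-based equal weights
are available where biomass is absent.

**Biotic novelty index (BNI).** Rao's Q with each pairwise distance
additionally weighted by a temporal coexistence weight
`c_ij = 1 − min(t_i, t_j, H)/H`, where `t` are regional residence times and
`H` is the familiarity horizon (default 527 y, the span from the 1492
status cut-off to the field campaign). The weight is 1 when the younger
species of a pair has just arrived and 0 once both species have coexisted
regionally for at least `H` years, so `0 ≤ BNI ≤ Rao's Q` always. The
linear decay is a documented default behind a strategy interface
(`strategy=` accepts any vectorized `f(t_min, horizon)`); residence is
measured per species and the pair minimum is used for the shared
coexistence period, a choice the API makes explicit rather than hiding.

## Function proxies

Three per-plot proxies are derived at the community, biogeographic-status,
functional-group and combined levels (suffixes `C, N, A, G, F, L, NG … AL`).

**Aboveground biomass (AGB).** Mean over the three replicate clip quadrats
of summed biomass, converted from a 20 × 50 cm quadrat to g m⁻²
(factor 10). Group AGB values are exactly additive to community AGB.

**Intrinsic water-use efficiency (iWUE).** From leaf δ¹³C via
discrimination theory:

    Δ¹³C = (δ_air − δ_plant) / (1 + δ_plant/1000),   δ_air = −8 ‰
    iWUE = (Ca/1.6) · (b′ − Δ¹³C)/(b′ − a),          Ca = 400 μmol mol⁻¹,
                                                     a = 4.4 ‰, b′ = 27 ‰

All four constants are configurable (`IsotopeConstants`). δ values use the
standard ‰ scaling `((R_sample/R_reference) − 1) × 1000`. The linear model
carries no mesophyll-conductance or post-photosynthetic corrections by
design.

**¹⁵N enrichment factor.** `Δδ¹⁵N = δ¹⁵N_plant − δ¹⁵N_soil` against the
plot-mean soil background (a `soil_statistic="median"` switch exists since
the field protocol does not fix the pooling rule). Higher values indicate a
more open N cycle with larger losses.

**Mixing model.** Group δ values are C-mass- (δ¹³C) or N-mass- (δ¹⁵N)
weighted over replicates; community δ values are pool-weighted over groups.
C4 material is excluded from every C-weighted average, because C4 δ¹³C does
not reflect water-use efficiency; the N side has no exclusion. Mixing is a
convex combination, so community values always lie within the span of the
contributing groups. Replicates are pooled by mass *before* group mixing
(the protocol specifies weighting by mass, not plain replicate means);
AGB, by contrast, is a plain replicate mean as stated. A group present in
the community but missing from the isotope table yields `NaN` proxies
(logged), never zeros — a zero δ is a real value, not absence.

## Light-response curves

Quantum yields `Fv/Fm = (Fm − F0)/Fm` and `ΔF/Fm′ = (Fm′ − F)/Fm′`;
instantaneous WUE `A/E` (μmol CO₂ per mmol H₂O; a `per_umol` flag applies
the mmol→μmol factor 1000); apparent electron transport rate
`ETR = 0.5 × 0.84 × ΔF/Fm′ × PPFD` (equal photosystem excitation, 16% leaf
reflection; both factors configurable).

The ETR–PPFD curve is fitted with the saturating rise to maximum
`y = a(1 − e^(−bx))`, giving `ETRmax = a` and the 90%-saturation point
`PPFDsat = ln(10)/b` in closed form (exact, no root finding). The
ΔF/Fm′–PPFD curve uses the exponential decay `y = a·e^(−bx)`; ΔF/Fm′ at
PPFDsat is the decay model evaluated at the rise fit's saturation point.
Some published conventions print the two formulas against the opposite
names; since a pure decay cannot produce a rise, this package assigns the
saturating form to ETR on physiological grounds and exposes
`form="literal"` to replicate the swapped reading verbatim.

Fitting is trust-region nonlinear least squares with `a ≥ 0, b > 0`,
initialized at `a₀ = max(y)` (rise) or `y` at the lowest PPFD (decay) and
`b₀ = 1/median(PPFD > 0)`, with up to 5 jittered restarts. Degenerate data
(e.g. an all-zero curve) yield a flagged non-converged fit, never a crash;
fewer than 4 points is an argument error for the 2-parameter model.

## Driver screen

A random-forest regressor screens 27 plot predictors (22 abiotic/urban
covariates counting each buffer family once, plus richness, Rao's Q, BNI,
moss and litter cover) for each proxy:

1. fit a forest (`n_trees`, default 2000) and record its explanatory R²
   (training) and a validation R² (5-fold CV, seed-controlled — the
   underlying field protocol does not define its validation scheme, so
   both numbers are reported side by side);
2. average permutation importance — the loss in R² when one predictor
   column is shuffled — over `n_importance_repeats` (default 100)
   re-randomizations;
3. compare each averaged importance against a permutation null: the
   response is permuted `n_permutations` (default 999) times, the full
   fit-plus-importance pipeline is re-run, and
   `p = (1 + #{null ≥ observed}) / (n_permutations + 1)`;
4. zero the importance of every predictor with `p > α` (default 0.05) and
   convert the survivors to shares of the explanatory R²
   (`share_k = imp_k/Σimp × R² × 100`), which sum to `R² × 100`;
5. report min-max-normalized partial-dependence curves for significant
   predictors (effect direction, not effect size), and optionally sum R²
   shares over named buffer-radius families (`buffer_group_importance`).

Design choices: a standard random forest with *permutation* (not impurity)
importance stands in for a conditional-inference forest — permutation
importance is the notion that remains approximately unbiased among the
strongly correlated buffer predictors, and no conditional-inference
implementation exists in the Python ecosystem. The null permutes the
response (a global-null test of "importance obtained just by chance"); a
per-predictor column-permutation mode is provided (`null_mode="predictor"`)
but is quadratically more expensive. The null pipeline uses the same number
of importance repeats as the observed statistic so that observed and null
values are exchangeable under the null — this is what makes the
permutation p-value calibrated. Missing predictor values are
median-imputed, within training folds during validation. For speed, all
column shuffles of an importance evaluation are scored through a single
stacked `predict` call; this changes nothing statistically.

## BEF statistics

Regressions of a proxy on species richness come in linear, log-linear and
saturating forms. Linear/log-linear report the slope on jointly min-max
normalized axes (identically `slope × range(x)/range(y)`), which makes
slopes comparable across studies with different units; a normalized slope
can be checked for inclusion in the [min, max] range of a two-column
`(study, slope)` collection (`synthesize_slopes`). The saturating default
is the asymptotic exponential `y = V(1 − e^(−kx))` — the same curve family
as the light-response fits — reporting the plateau `V`, half-saturation
`ln2/k` and the richness at 90% of the plateau `ln10/k`; a
Michaelis–Menten alternative `Vx/(K + x)` is selectable, and the fitted
form is always reported explicitly.

Group comparisons use rank statistics for small plot samples:
Mann–Whitney U for two groups, Kruskal–Wallis plus pairwise Mann–Whitney
with Bonferroni adjustment (Holm optional) for three or more, and
Spearman's ρ for correlations; all are tie-corrected and invariant to
monotone transformations of the response.

## Synthetic study generator

The generator emulates the field design so every stage has a recoverable
ground truth. Defaults are the study conditions: 20 plots, 3 replicate
quadrats, plot richness uniform on 13–48 from a 120-species regional pool,
one third of forbs alien (alien graminoids/legumes ten times rarer), C4
species a small graminoid minority capped at 5% of the pool, alien
residence times uniform on [0, 527] y and natives at or above the horizon.
Covariates are drawn inside the observed min–max bounds of each parameter;
a latent per-plot urban-intensity factor (weight 0.7 against independent
noise) drives every buffer-radius member of the impervious/FAR/population/
road/railway families, negatively drives grassland share and distance
variables, and weakly warms the climate columns — reproducing the
collinearity structure the screen must disentangle.

Community biomass follows the planted saturating relation
`AGB(S) = 350·(1 − e^(−kS))` g m⁻² with 90% saturation at 30 species,
interpolated toward a flat 280 g m⁻² level as `richness_agb_effect → 0`;
plot-level lognormal noise has CV 0.12 and replicates re-draw the total
with CV 0.30 (the observed within-plot replicate variability). The alien
biomass share is pinned near 13.1%. Isotope values are generated backwards
through the published chains: a target group iWUE
(base 50.8 μmol mol⁻¹, graminoids highest) responds to sky view factor
(+30 per unit SVF) and soil water (−20 per unit Wc) and is inverted to a
leaf δ¹³C; plant δ¹⁵N is the plot soil background (N(2, 1) ‰) plus a base
enrichment of −3.43 ‰, a functional-group offset (graminoids lowest) and
an urban response (+4 ‰ per unit of the observable composite of the 500-m
urban covariates). Noise SDs (iWUE 1.5 μmol mol⁻¹, δ¹⁵N 0.8 ‰) are set so
the planted links are clearly recoverable at the stated study sizes
without being trivial. Gaussian noise is used throughout, truncated where
physical bounds exist (yields to [0, 1], biomass ≥ 0).

Light curves are generated from the true rise-to-max ETR model with
ETR-scale Gaussian noise converted back to ΔF/Fm′ (the analytic small-x
limit `ab/0.42` is used at PPFD 0) over the standard 8 light steps
0–2000 μmol m⁻² s⁻¹.

What the generator does *not* emulate: spatial structure (plots are
exchangeable rows, not Berlin geography), trait covariance and redundancy
(traits are independent draws, so synthetic Rao's Q magnitudes exceed
field values), species turnover along the urban gradient, and seasonal
dynamics. Passing recovery tests therefore demonstrates the correctness of
the estimators under the planted model, not performance guarantees on real
field data.

All generation is deterministic: every operation derives its stream from
the scenario seed via independent `SeedSequence` spawn keys, and identical
scenarios yield bit-identical tables.

## Pipeline and problem sizes

`run_pipeline` chains diversity → proxies → optional light-curve fits →
driver screens → BEF regressions, writing tidy CSVs, a JSON manifest
(config, derived per-stage seeds, outputs, skip reasons) and a plain-text
summary in which every number names its source file. A plant group enters
the driver screen only if present in ≥ 30% of plots (configurable); the
field analysis likewise could not fit models for sparse groups, without
stating a rule. Stage failures are isolated and dependents are skipped
with provenance.

The test suite and the acceptance script run the screen at desk settings —
50 trees, 3 importance repeats, 99 permutations, 50 null replicates —
chosen as the package's own scaled-down protocol for the calibration
experiments; the full-fidelity settings (2000/100/999) are plain
configuration. Calibration tolerances are decided a priori: the null
significant-predictor fraction must sit within a 3σ binomial band around
α with a ×2 design-effect allowance for the within-replicate correlation
induced by the shared permutation null.

## Known limitations

- The conditional-inference forest is approximated, not reproduced; exact
  R² values from any particular forest implementation are not a target.
- Gower distances assume trait ranges are estimable from the supplied
  table; with very few species the range normalization is noisy.
- The BNI temporal weight is a linear-decay default behind a strategy
  interface; alternative published decay forms can be plugged in without
  touching the index code.
- `null_mode="predictor"` refits one forest per predictor per permutation
  and is impractical beyond small tables.
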