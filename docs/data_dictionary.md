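# Data dictionary

All files are UTF-8 CSV, comma delimiter, `.` decimal. Units are listed
here, never in headers.

## Input bundle

### species.csv
| column | type | description |
|---|---|---|
| species | token | unique species id |
| status | `native` / `alien` | biogeographic status (aliens = neophytes, introduced after 1492) |
| functional_group | `graminoid` / `forb` / `legume` | functional group |
| pathway | `C3` / `C4` | photosynthetic pathway |
| residence_time | years ≥ 0 | time since regional arrival |

### traits.csv
One row per species; exactly the 12 trait columns below. Empty cells mark
missing values (handled by pairwise deletion in the Gower distance).

numeric: `height_m` (m), `sla_mm2_mg` (mm² mg⁻¹), `leaf_area_mm2` (mm²),
`seed_mass_mg` (mg), `dispersal_length_mm` (mm), `leaf_n_mg_g` (mg g⁻¹).
categorical: `life_form`, `flower_color`, `flower_class`, `clonal_growth`,
`n_fixation` (`yes`/`no`), `mycorrhiza`.

### plots.csv
One row per plot. `age` is `O` (old, pre-1945 grassland) / `N` (new).
Buffer families carry suffixes `_100/_500/_1000/_5000` (buffer radius, m):
`grassland_*` (share 0–1), `impervious_*` (%), `far_*` (floor-area ratio),
`popd_*` (inhabitants ha⁻¹), `roadd_*` (km), `railwd_*` (km). Singles:
`size_patch` (m²), `rdist`/`railwdist` (m), `airt_longterm` (°C),
`urbclim` (class 0–4), `airt` (°C), `airrh` (%), `svf` (0–1),
`soil_n` (g kg⁻¹), `soil_cu`/`soil_zn`/`soil_cd`/`soil_pb`/`soil_ni`
(mg kg⁻¹), `soil_wc` (gravimetric fraction), `moss_cover`/`litter_cover`
(%).

### communities.csv
| column | type | description |
|---|---|---|
| plot | token | plot id (must exist in plots.csv) |
| replicate | int | clip-quadrat replicate (1..3) |
| species | token | species id (must exist in species.csv) |
| biomass_g | g ≥ 0 | dry biomass in the 20 × 50 cm quadrat |

### isotopes.csv
Keyed by (plot, replicate, group), where `group` is
`<status>_<functional_group>` (e.g. `native_forb`). Rows flagged
`c4 = True` carry C4 material of that group and are excluded from all
C-weighted δ¹³C averages.

| column | unit |
|---|---|
| dry_mass_g | g |
| c_percent, n_percent | % of dry mass |
| d13c | ‰ vs VPDB |
| d15n | ‰ vs air-N₂ |

### soil.csv
`plot`, `replicate`, `d15n_soil` (‰ vs air-N₂).

### light curves (optional, long format)
`individual`, `ppfd` (μmol m⁻² s⁻¹), `yield` (ΔF/Fm′, 0–1).

### slopes.csv (optional)
`study`, `slope` — min-max-normalized richness→AGB regression slopes from
other grassland studies.

## Outputs

- `diversity.csv`: per plot `richness`, `prop_alien`, `rao_q`, `bni`.
- `proxies.csv`: per plot `AGB_*` (g m⁻²), `iWUE_*` (μmol mol⁻¹),
  `dd15N_*` (‰) for suffixes `C, N, A, G, F, L, NG, NF, NL, AG, AF, AL`.
- `screen_<response>.csv`: per predictor `mean_importance`, `p_value`,
  `significant`, `importance` (zeroed if non-significant),
  `r2_contribution_pct`, plus `model_r2`, `validation_r2`.
- `pdp_<response>.csv`: `predictor`, `grid`, `pdp` (min-max normalized).
- `light_fits.csv`: per individual × target `a`, `b`, `etr_max`,
  `ppfd_sat`, `yield_at_sat`, `rss`, `converged`.
- `bef.csv`: per response/form regression summaries.
- `manifest.json`, `summary.txt`: provenance and headline numbers.
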