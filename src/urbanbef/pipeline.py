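"""End-to-end orchestration of the analysis chain.

diversity -> function proxies -> (optional) light-curve fits -> driver
screens per proxy and plant group -> biodiversity-function regressions.
Each stage writes a tidy CSV; a machine-readable manifest records the
configuration, derived seeds and outputs, and a plain-text summary lists
the headline quantities with the files they come from. Stage failures are
isolated: dependents are skipped with a logged reason, never a crash.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .bef import bef_regression, synthesize_slopes
from .diversity import plot_diversity_table
from .drivers import DriverScreen
from .io import Bundle, RunConfig, read_bundle, write_bundle
from .isotopes import GROUP_POOLS, IsotopeConstants, aggregate_plot
from .light import LightCurve, fit_curve_pair
from .synthetic import SyntheticScenario, simulate_bundle

__all__ = ["run_pipeline", "build_predictor_table", "select_responses"]

log = logging.getLogger(__name__)

PROXIES = ("AGB", "iWUE", "dd15N")
RESPONSE_SETS = {
    "community": ("C",),
    "status": ("C", "N", "A"),
    "functional": ("C", "N", "A", "G", "F", "L"),
    "combined": tuple(GROUP_POOLS),
}


def _stage_seed(global_seed: int, k: int) -> int:
    ss = np.random.SeedSequence(global_seed, spawn_key=(k,))
    return int(ss.generate_state(1)[0] % (2**31 - 1))


def build_predictor_table(plots: pd.DataFrame, diversity: pd.DataFrame) -> pd.DataFrame:
    """Assemble the numeric predictor matrix for the driver screens.

    Plot covariates (habitat-continuity age encoded 0 = old, 1 = new)
    joined with the biodiversity predictors (richness, Rao's Q, BNI).
    Moss and litter cover already sit in the covariate table.
    """
    X = plots.copy()
    if "age" in X.columns:
        X["age_new"] = (X["age"].astype(str).str.upper() == "N").astype(float)
        X = X.drop(columns=["age"])
    X = X.select_dtypes(include=[np.number])
    div = diversity[["richness", "rao_q", "bni"]]
    return X.join(div, how="inner")


def select_responses(proxies: pd.DataFrame, which, min_presence: float) -> tuple[list, dict]:
    """Pick screenable proxy columns; sparse plant groups are skipped.

    A group is screened only if its proxy is observed (AGB > 0 or a finite
    delta-derived value) in at least ``min_presence`` of the plots.
    Returns (selected columns, {skipped column: reason}).
    """
    if isinstance(which, str):
        suffixes = RESPONSE_SETS[which]
        candidates = [f"{p}_{s}" for p in PROXIES for s in suffixes]
    else:
        candidates = list(which)
    selected, skipped = [], {}
    n = len(proxies)
    for col in candidates:
        if col not in proxies.columns:
            skipped[col] = "column not present in proxy table"
            continue
        v = proxies[col]
        present = (v > 0) if col.startswith("AGB") else v.notna()
        frac = float(present.sum()) / n if n else 0.0
        if frac < min_presence:
            skipped[col] = f"group present in {frac:.0%} of plots (< {min_presence:.0%})"
            continue
        vv = v.dropna()
        if len(vv) < 10 or np.ptp(vv.to_numpy()) == 0:
            skipped[col] = "fewer than 10 observations or constant response"
            continue
        selected.append(col)
    return selected, skipped


def _read_light_curves(path) -> list[LightCurve]:
    df = pd.read_csv(path)
    curves = []
    for ind, sub in df.groupby("individual", sort=True):
        sub = sub.sort_values("ppfd")
        curves.append(LightCurve(individual=str(ind),
                                 ppfd=sub["ppfd"].to_numpy(float),
                                 yields=sub["yield"].to_numpy(float)))
    return curves


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage and write the report bundle to ``config.outdir``.

    Returns the manifest dict (config, seeds, stage outputs, skipped
    models with reasons, failures).
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package": "urbanbef",
        "version": __version__,
        "config": config.to_dict(),
        "seed": config.seed,
        "stage_seeds": {},
        "outputs": {},
        "skipped": {},
        "failures": {},
    }

    # ---- input -----------------------------------------------------------
    if config.input_dir is None:
        scen = SyntheticScenario(**{"seed": config.seed, **config.scenario})
        sim = simulate_bundle(scen)
        write_bundle(sim, outdir / "inputs")
        bundle = Bundle(catalog=sim["catalog"], plots=sim["plots"],
                        communities=sim["communities"],
                        isotopes=sim["isotopes"], soil=sim["soil"])
        manifest["outputs"]["inputs"] = str(outdir / "inputs")
    else:
        bundle = read_bundle(config.input_dir)

    consts = IsotopeConstants(
        delta13c_air=config.constants.delta13c_air, ca=config.constants.ca,
        a=config.constants.a, b_prime=config.constants.b_prime,
    )

    # ---- diversity -------------------------------------------------------
    diversity = None
    try:
        diversity = plot_diversity_table(bundle.communities, bundle.catalog)
        path = outdir / "diversity.csv"
        diversity.to_csv(path)
        manifest["outputs"]["diversity"] = path.name
    except Exception as err:  # stage isolation
        log.exception("diversity stage failed")
        manifest["failures"]["diversity"] = str(err)

    # ---- function proxies ------------------------------------------------
    proxies = None
    try:
        proxies = aggregate_plot(bundle.communities, bundle.isotopes,
                                 bundle.soil, bundle.catalog, consts)
        path = outdir / "proxies.csv"
        proxies.to_csv(path)
        manifest["outputs"]["proxies"] = path.name
    except Exception as err:
        log.exception("proxy stage failed")
        manifest["failures"]["proxies"] = str(err)

    # ---- light curves (optional) ----------------------------------------
    if config.light_curves:
        try:
            rows = []
            for curve in _read_light_curves(config.light_curves):
                etr_fit, yield_fit = fit_curve_pair(curve)
                for f in (etr_fit, yield_fit):
                    rows.append({
                        "individual": curve.individual, "target": f.target,
                        "form": f.form, "a": f.a, "b": f.b,
                        "etr_max": f.etr_max, "ppfd_sat": f.ppfd_sat,
                        "yield_at_sat": f.yield_at_sat, "rss": f.rss,
                        "converged": f.converged,
                    })
            path = outdir / "light_fits.csv"
            pd.DataFrame(rows).to_csv(path, index=False)
            manifest["outputs"]["light_fits"] = path.name
        except Exception as err:
            log.exception("light-curve stage failed")
            manifest["failures"]["light_curves"] = str(err)

    # ---- driver screens --------------------------------------------------
    if proxies is not None and diversity is not None:
        X = build_predictor_table(bundle.plots, diversity)
        selected, skipped = select_responses(proxies, config.responses,
                                             config.min_group_presence)
        for col, reason in skipped.items():
            log.info("skipping driver screen for %s: %s", col, reason)
        manifest["skipped"].update(skipped)
        for k, col in enumerate(selected):
            try:
                y = proxies[col].reindex(X.index)
                ok = y.notna()
                seed = _stage_seed(config.seed, 100 + k)
                manifest["stage_seeds"][f"screen_{col}"] = seed
                screen = DriverScreen(random_state=seed, **config.screen)
                screen.fit(X.loc[ok], y.loc[ok].to_numpy())
                res = screen.result_frame()
                res.insert(0, "response", col)
                res["model_r2"] = screen.model_r2_
                res["validation_r2"] = screen.validation_r2_
                path = outdir / f"screen_{col}.csv"
                res.to_csv(path, index=False)
                manifest["outputs"][f"screen_{col}"] = path.name
                pdp_rows = []
                for name, sig in zip(screen.feature_names_in_, screen.significant_):
                    if not sig:
                        continue
                    try:
                        grid, resp = screen.partial_dependence(name)
                    except ValueError:
                        continue
                    for g, r in zip(grid, resp):
                        pdp_rows.append({"response": col, "predictor": name,
                                         "grid": g, "pdp": r})
                if pdp_rows:
                    path = outdir / f"pdp_{col}.csv"
                    pd.DataFrame(pdp_rows).to_csv(path, index=False)
                    manifest["outputs"][f"pdp_{col}"] = path.name
            except Exception as err:
                log.exception("driver screen for %s failed", col)
                manifest["failures"][f"screen_{col}"] = str(err)
    else:
        manifest["skipped"]["driver_screens"] = "upstream stage failed"

    # ---- biodiversity-function regressions ------------------------------
    if proxies is not None and diversity is not None:
        try:
            rich = diversity["richness"].reindex(proxies.index)
            rows = []
            for col in ("AGB_C", "iWUE_C", "dd15N_C"):
                y = proxies[col]
                ok = y.notna() & rich.notna()
                lin = bef_regression(rich[ok], y[ok], form="linear")
                rows.append({"response": col, "form": "linear",
                             "slope": lin.slope, "normalized_slope": lin.normalized_slope,
                             "p_value": lin.p_value, "r2": lin.r2,
                             "plateau": None, "saturation_richness": None})
                if col == "AGB_C" and config.bef_form == "saturating":
                    sat = bef_regression(rich[ok], y[ok], form="saturating")
                    rows.append({"response": col, "form": "saturating",
                                 "slope": None, "normalized_slope": None,
                                 "p_value": None, "r2": sat.r2,
                                 "plateau": sat.plateau,
                                 "saturation_richness": sat.saturation_richness})
            bef_table = pd.DataFrame(rows)
            path = outdir / "bef.csv"
            bef_table.to_csv(path, index=False)
            manifest["outputs"]["bef"] = path.name
            if config.slopes:
                coll = pd.read_csv(config.slopes)
                query = bef_table.loc[
                    (bef_table["response"] == "AGB_C")
                    & (bef_table["form"] == "linear"),
                    "normalized_slope"].iloc[0]
                verdict = synthesize_slopes(coll, float(query))
                path = outdir / "slope_synthesis.json"
                path.write_text(json.dumps(verdict, indent=2, sort_keys=True))
                manifest["outputs"]["slope_synthesis"] = path.name
        except Exception as err:
            log.exception("regression stage failed")
            manifest["failures"]["bef"] = str(err)
    else:
        manifest["skipped"]["bef"] = "upstream stage failed"

    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True, default=str))
    _write_summary(outdir, manifest)
    return manifest


def _write_summary(outdir: Path, manifest: dict) -> None:
    lines = [f"urbanbef {manifest['version']} run (seed {manifest['seed']})", ""]
    if "proxies" in manifest["outputs"]:
        prox = pd.read_csv(outdir / "proxies.csv", index_col="plot")
        agb_c = prox["AGB_C"]
        alien_share = float(prox["AGB_A"].sum() / agb_c.sum() * 100) if agb_c.sum() else float("nan")
        lines += [
            f"plots: {len(prox)}  [proxies.csv]",
            f"mean community AGB: {agb_c.mean():.1f} g m-2  [proxies.csv]",
            f"alien share of community AGB: {alien_share:.1f}%  [proxies.csv]",
            f"mean community iWUE: {prox['iWUE_C'].mean():.2f} umol mol-1  [proxies.csv]",
            f"mean community dd15N: {prox['dd15N_C'].mean():.2f} per mil  [proxies.csv]",
        ]
    for key, fname in sorted(manifest["outputs"].items()):
        if key.startswith("screen_"):
            df = pd.read_csv(outdir / fname)
            sig = df[df["significant"]]
            top = (sig.sort_values("r2_contribution_pct", ascending=False)
                   ["predictor"].head(3).tolist())
            lines.append(
                f"{key[7:]}: model R2 {df['model_r2'].iloc[0]:.2f}, "
                f"validation R2 {df['validation_r2'].iloc[0]:.2f}, "
                f"top predictors {top}  [{fname}]")
    for col, reason in manifest["skipped"].items():
        lines.append(f"skipped {col}: {reason}")
    for col, err in manifest["failures"].items():
        lines.append(f"FAILED {col}: {err}")
    (outdir / "summary.txt").write_text("\n".join(lines) + "\n")
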