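"""Biodiversity-ecosystem-functioning regressions and comparison tests.

Regression of a function proxy (AGB, iWUE, dd15N) on species richness with
linear, log-linear and saturating forms; min-max-normalized slopes that can
be synthesized against slope collections from other grassland studies; and
the rank-based group comparisons and correlations used on small plot
samples (Mann-Whitney / Kruskal-Wallis with adjusted pairwise tests,
Spearman's rho).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import curve_fit
from sklearn.base import BaseEstimator, RegressorMixin
from statsmodels.stats.multitest import multipletests

__all__ = [
    "minmax_normalize",
    "BEFRegression",
    "BEFRegressionResult",
    "bef_regression",
    "synthesize_slopes",
    "RankTestResult",
    "rank_tests",
    "rank_correlation",
]


def minmax_normalize(x) -> np.ndarray:
    """(x - min)/(max - min); raises on a constant vector."""
    v = np.asarray(x, dtype=float)
    lo, hi = np.nanmin(v), np.nanmax(v)
    if hi <= lo:
        raise ValueError("degenerate normalization: constant vector")
    return (v - lo) / (hi - lo)


def _saturating_exponential(x, v, k):
    return v * (1.0 - np.exp(-k * np.asarray(x, dtype=float)))


def _michaelis_menten(x, v, k):
    x = np.asarray(x, dtype=float)
    return v * x / (k + x)


@dataclass
class BEFRegressionResult:
    """Summary of one richness-function regression.

    For linear / log-linear forms, ``normalized_slope`` is the slope on
    jointly min-max normalized axes (equal to slope * range(x)/range(y)).
    The saturating forms report ``plateau``, ``half_saturation`` and
    ``saturation_richness`` (richness at 90% of the plateau) instead.
    """

    form: str
    coefficients: dict
    r2: float
    p_value: float | None = None
    slope: float | None = None
    normalized_slope: float | None = None
    plateau: float | None = None
    half_saturation: float | None = None
    saturation_richness: float | None = None


class BEFRegression(BaseEstimator, RegressorMixin):
    """Richness-function regression as a scikit-learn estimator.

    Parameters
    ----------
    form : 'linear' (y ~ x), 'loglinear' (y ~ log x) or 'saturating'.
    saturating_form : 'exponential' (V(1 - e^{-kx}), default) or
        'michaelis' (Vx/(K + x)).
    """

    def __init__(self, form: str = "linear", saturating_form: str = "exponential"):
        self.form = form
        self.saturating_form = saturating_form

    def fit(self, X, y):
        x = np.asarray(X, dtype=float).reshape(-1)
        y = np.asarray(y, dtype=float).reshape(-1)
        if x.shape != y.shape:
            raise ValueError("X and y must align")
        if len(x) < 5:
            raise ValueError("need at least 5 plots")
        self.n_ = len(x)
        if self.form in ("linear", "loglinear"):
            if self.form == "loglinear":
                if np.any(x <= 0):
                    raise ValueError("log-linear form requires positive richness")
                xr = np.log(x)
            else:
                xr = x
            res = stats.linregress(xr, y)
            self.slope_ = float(res.slope)
            self.intercept_ = float(res.intercept)
            self.r2_ = float(res.rvalue**2)
            self.pvalue_ = float(res.pvalue)
            rx = np.ptp(xr)
            ry = np.ptp(y)
            if rx == 0 or ry == 0:
                raise ValueError("degenerate normalization: constant axis")
            self.normalized_slope_ = float(res.slope * rx / ry)
            self.plateau_ = None
            self.half_saturation_ = None
            self.saturation_richness_ = None
        elif self.form == "saturating":
            if self.saturating_form == "exponential":
                model = _saturating_exponential
                p0 = (max(float(np.max(y)), 1e-9), 1.0 / max(float(np.mean(x)), 1e-9))
            elif self.saturating_form == "michaelis":
                model = _michaelis_menten
                p0 = (max(float(np.max(y)), 1e-9), max(float(np.median(x)), 1e-9))
            else:
                raise ValueError(f"unknown saturating_form {self.saturating_form!r}")
            popt, _ = curve_fit(
                model, x, y, p0=p0,
                bounds=([0.0, 1e-12], [np.inf, np.inf]), maxfev=20000,
            )
            self.coef_sat_ = tuple(float(v) for v in popt)
            resid = y - model(x, *popt)
            ss_res = float(resid @ resid)
            ss_tot = float(((y - y.mean()) ** 2).sum())
            self.r2_ = 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")
            self.pvalue_ = None
            self.slope_ = None
            self.normalized_slope_ = None
            v, k = self.coef_sat_
            self.plateau_ = v
            if self.saturating_form == "exponential":
                self.half_saturation_ = float(np.log(2.0) / k)
                self.saturation_richness_ = float(np.log(10.0) / k)
            else:
                self.half_saturation_ = k
                self.saturation_richness_ = 9.0 * k
        else:
            raise ValueError(f"unknown form {self.form!r}")
        return self

    def predict(self, X):
        x = np.asarray(X, dtype=float).reshape(-1)
        if self.form == "linear":
            return self.intercept_ + self.slope_ * x
        if self.form == "loglinear":
            return self.intercept_ + self.slope_ * np.log(x)
        model = (_saturating_exponential if self.saturating_form == "exponential"
                 else _michaelis_menten)
        return model(x, *self.coef_sat_)

    def result(self) -> BEFRegressionResult:
        if self.form in ("linear", "loglinear"):
            coefs = {"slope": self.slope_, "intercept": self.intercept_}
        else:
            coefs = {"plateau": self.coef_sat_[0], "rate": self.coef_sat_[1]}
        return BEFRegressionResult(
            form=self.form,
            coefficients=coefs,
            r2=self.r2_,
            p_value=self.pvalue_,
            slope=self.slope_,
            normalized_slope=self.normalized_slope_,
            plateau=self.plateau_,
            half_saturation=self.half_saturation_,
            saturation_richness=self.saturation_richness_,
        )


def bef_regression(richness, proxy, form: str = "linear",
                   saturating_form: str = "exponential") -> BEFRegressionResult:
    """Fit one biodiversity-function regression and summarize it."""
    est = BEFRegression(form=form, saturating_form=saturating_form)
    return est.fit(richness, proxy).result()


def synthesize_slopes(collection: pd.DataFrame, query_slope: float) -> dict:
    """Compare a normalized regression slope with a collection of study
    slopes; the verdict is true iff the query lies in [min, max].

    ``collection`` needs columns ``study`` and ``slope`` (a two-column CSV
    of digitized literature slopes drops in directly).
    """
    if len(collection) == 0:
        raise ValueError("empty slope collection")
    slopes = collection["slope"].to_numpy(dtype=float)
    lo, hi = float(slopes.min()), float(slopes.max())
    return {
        "query_slope": float(query_slope),
        "min": lo,
        "max": hi,
        "median": float(np.median(slopes)),
        "n_studies": int(len(slopes)),
        "within_range": bool(lo <= query_slope <= hi),
    }


@dataclass
class RankTestResult:
    """Omnibus rank test with optional adjusted pairwise comparisons."""

    test: str
    statistic: float
    p_value: float
    n_groups: int
    pairwise: pd.DataFrame | None = None


def rank_tests(values, groups, alpha: float = 0.05,
               adjust: str = "bonferroni") -> RankTestResult:
    """Rank-based group comparison.

    Two groups: two-sided Mann-Whitney U (tie-corrected). Three or more:
    Kruskal-Wallis omnibus; if significant at ``alpha``, all pairwise
    Mann-Whitney tests with multiplicity-adjusted p-values ('bonferroni'
    default, 'holm' available).
    """
    v = np.asarray(values, dtype=float)
    g = np.asarray(groups)
    if v.shape != g.shape:
        raise ValueError("values and groups must align")
    labels = pd.unique(g)
    if len(labels) < 2:
        raise ValueError("need at least 2 groups")
    samples = [v[g == lab] for lab in labels]
    for lab, s in zip(labels, samples):
        if len(s) < 2:
            raise ValueError(f"group {lab!r} has fewer than 2 observations")
    if len(labels) == 2:
        stat, p = stats.mannwhitneyu(samples[0], samples[1],
                                     alternative="two-sided")
        return RankTestResult("mann-whitney", float(stat), float(p), 2)
    stat, p = stats.kruskal(*samples)
    pairwise = None
    if p < alpha:
        rows = []
        for (i, a), (j, b) in combinations(enumerate(labels), 2):
            u, pu = stats.mannwhitneyu(samples[i], samples[j],
                                       alternative="two-sided")
            rows.append({"group_a": a, "group_b": b, "statistic": float(u),
                         "p_raw": float(pu)})
        table = pd.DataFrame(rows)
        table["p_adjusted"] = multipletests(table["p_raw"], method=adjust)[1]
        pairwise = table
    return RankTestResult("kruskal-wallis", float(stat), float(p),
                          len(labels), pairwise)


def rank_correlation(x, y) -> tuple[float, float, int]:
    """Spearman rank correlation with tie handling: (rho, two-sided p, n)."""
    xv = np.asarray(x, dtype=float)
    yv = np.asarray(y, dtype=float)
    if xv.shape != yv.shape:
        raise ValueError("x and y must align")
    ok = np.isfinite(xv) & np.isfinite(yv)
    xv, yv = xv[ok], yv[ok]
    if len(xv) < 4:
        raise ValueError("need at least 4 paired observations")
    if np.ptp(xv) == 0 or np.ptp(yv) == 0:
        raise ValueError("undefined correlation: constant input")
    rho, p = stats.spearmanr(xv, yv)
    return float(rho), float(p), int(len(xv))
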