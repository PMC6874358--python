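"""Chlorophyll-a fluorescence and gas-exchange ecophysiology.

Quantum yields (Fv/Fm, dF/Fm'), instantaneous water-use efficiency (A/E),
apparent electron transport rate (ETR), and nonlinear light-response-curve
fits with their cardinal points (ETRmax, PPFDsat, yield at PPFDsat).

The ETR-PPFD curve is fitted with a saturating exponential rise to maximum
y = a(1 - exp(-b x)) whose asymptote a is ETRmax and whose 90%-saturation
point is PPFDsat = ln(10)/b; the dF/Fm'-PPFD curve is fitted with the
exponential decay y = a exp(-b x). Either form can be forced on either
target via ``form=`` for literal replication of alternative conventions.
"""

from __future__ import annotations

from dataclasses import dataclass
import numpy as np
from scipy.optimize import curve_fit
from sklearn.base import BaseEstimator, RegressorMixin

__all__ = [
    "PPFD_LEVELS",
    "PSII_FRACTION",
    "ABSORPTANCE",
    "fvfm",
    "effective_yield",
    "instant_wue",
    "etr",
    "LightCurve",
    "CurveFit",
    "FitFailure",
    "rise_to_max",
    "exp_decay",
    "LightResponseRegression",
    "fit_light_curve",
]

#: Standard actinic light steps of an instant light curve (umol m^-2 s^-1).
PPFD_LEVELS = (0.0, 100.0, 300.0, 600.0, 900.0, 1200.0, 1500.0, 2000.0)

PSII_FRACTION = 0.5  # equal excitation of photosystems II and I
ABSORPTANCE = 0.84  # 16% average leaf reflection


def fvfm(f0: float, fm: float) -> float:
    """Maximum potential quantum yield of PSII: (Fm - F0)/Fm."""
    if fm <= 0:
        raise ZeroDivisionError("Fm must be > 0")
    if f0 < 0 or f0 > fm:
        raise ValueError("require 0 <= F0 <= Fm")
    return (fm - f0) / fm


def effective_yield(f: float, fm_prime: float) -> float:
    """Effective quantum yield of PSII in the light: (Fm' - F)/Fm'."""
    if fm_prime <= 0:
        raise ZeroDivisionError("Fm' must be > 0")
    if f < 0 or f > fm_prime:
        raise ValueError("require 0 <= F <= Fm'")
    return (fm_prime - f) / fm_prime


def instant_wue(a: float, e: float, per_umol: bool = False) -> float:
    """Instantaneous water-use efficiency A/E.

    A in umol CO2 m^-2 s^-1, E in mmol H2O m^-2 s^-1; the ratio is umol
    CO2 per mmol H2O. ``per_umol=True`` divides by 1000 to report umol CO2
    per umol H2O (the mmol -> umol harmonization).
    """
    if e <= 0:
        raise ValueError("transpiration rate E must be > 0")
    r = a / e
    return r / 1000.0 if per_umol else r


def etr(
    yield_: float,
    ppfd: float,
    psii_fraction: float = PSII_FRACTION,
    absorptance: float = ABSORPTANCE,
):
    """Apparent electron transport rate: 0.5 * 0.84 * (dF/Fm') * PPFD."""
    y = np.asarray(yield_, dtype=float)
    q = np.asarray(ppfd, dtype=float)
    if np.any(y < 0) or np.any(y > 1):
        raise ValueError("yield must lie in [0, 1]")
    if np.any(q < 0):
        raise ValueError("PPFD must be >= 0")
    out = psii_fraction * absorptance * y * q
    return float(out) if out.ndim == 0 else out


@dataclass
class LightCurve:
    """One individual's instant light curve: strictly increasing PPFD steps
    with the effective quantum yield dF/Fm' measured at each step."""

    individual: str
    ppfd: np.ndarray
    yields: np.ndarray

    def __post_init__(self) -> None:
        self.ppfd = np.asarray(self.ppfd, dtype=float)
        self.yields = np.asarray(self.yields, dtype=float)
        if self.ppfd.shape != self.yields.shape:
            raise ValueError("ppfd and yields must align")
        if np.any(self.ppfd < 0):
            raise ValueError("PPFD must be >= 0")
        if np.any(np.diff(self.ppfd) <= 0):
            raise ValueError("PPFD must be strictly increasing")
        if np.any((self.yields < 0) | (self.yields > 1)):
            raise ValueError("yields must lie in [0, 1]")

    def etr(self) -> np.ndarray:
        return etr(self.yields, self.ppfd)


def rise_to_max(x, a, b):
    """Saturating exponential rise to maximum: a(1 - exp(-b x))."""
    return a * (1.0 - np.exp(-b * np.asarray(x, dtype=float)))


def exp_decay(x, a, b):
    """Exponential decay: a exp(-b x)."""
    return a * np.exp(-b * np.asarray(x, dtype=float))


class FitFailure(RuntimeError):
    """Nonlinear fit did not converge after restarts; carries diagnostics."""

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


@dataclass
class CurveFit:
    """Fitted light-response curve and its cardinal points.

    ``etr_max``/``ppfd_sat`` are populated for the rise-to-max form
    (ETRmax = a, PPFDsat = ln(10)/b, the PPFD at 90% of the asymptote);
    ``yield_at_sat`` requires a companion yield fit (see
    :func:`fit_curve_pair`).
    """

    target: str
    form: str
    a: float
    b: float
    rss: float
    n_points: int
    converged: bool
    etr_max: float | None = None
    ppfd_sat: float | None = None
    yield_at_sat: float | None = None

    def predict(self, x):
        f = rise_to_max if self.form == "rise_to_max" else exp_decay
        return f(x, self.a, self.b)


class LightResponseRegression(BaseEstimator, RegressorMixin):
    """Nonlinear least-squares light-response fit (sklearn estimator).

    Parameters
    ----------
    form : 'rise_to_max' (a(1-e^{-bx}), for ETR) or 'exp_decay'
        (a e^{-bx}, for dF/Fm').
    max_restarts : jittered re-initializations tried on non-convergence.
    random_state : seed for the restart jitter.

    Attributes (after fit)
    ----------------------
    a_, b_ : fitted coefficients (b_ > 0).
    etr_max_, ppfd_sat_ : cardinal points (rise-to-max form only).
    rss_, converged_ : residual sum of squares and convergence flag.
    """

    def __init__(self, form: str = "rise_to_max", max_restarts: int = 5,
                 random_state: int | None = None):
        self.form = form
        self.max_restarts = max_restarts
        self.random_state = random_state

    def _model(self):
        if self.form == "rise_to_max":
            return rise_to_max
        if self.form == "exp_decay":
            return exp_decay
        raise ValueError(f"unknown form {self.form!r}")

    def fit(self, X, y):
        x = np.asarray(X, dtype=float).reshape(-1)
        y = np.asarray(y, dtype=float).reshape(-1)
        if x.shape != y.shape:
            raise ValueError("X and y must align")
        if len(x) < 4:
            raise ValueError("need at least 4 points for the 2-parameter fit")
        model = self._model()
        xpos = x[x > 0]
        b0 = 1.0 / np.median(xpos) if len(xpos) else 1e-3
        if self.form == "rise_to_max":
            a0 = max(float(np.max(y)), 1e-12)
        else:
            a0 = max(float(y[np.argmin(x)]), 1e-12)
        rng = np.random.default_rng(self.random_state)
        last_err = None
        for attempt in range(self.max_restarts + 1):
            if attempt == 0:
                p0 = (a0, b0)
            else:
                p0 = (a0 * rng.uniform(0.3, 3.0), b0 * rng.uniform(0.3, 3.0))
            try:
                popt, _ = curve_fit(
                    model, x, y, p0=p0,
                    bounds=([0.0, 1e-12], [np.inf, np.inf]),
                    maxfev=20000,
                )
            except (RuntimeError, ValueError) as err:  # no convergence
                last_err = err
                continue
            self.a_, self.b_ = float(popt[0]), float(popt[1])
            resid = y - model(x, *popt)
            self.rss_ = float(resid @ resid)
            self.converged_ = True
            break
        else:
            # degenerate data (e.g. all-zero ETR): flag, never crash
            self.a_, self.b_ = 0.0, float("nan")
            self.rss_ = float(((y - y.mean()) ** 2).sum())
            self.converged_ = False
            self._last_error = last_err
        self.n_points_ = len(x)
        if self.form == "rise_to_max" and self.converged_:
            self.etr_max_ = self.a_
            self.ppfd_sat_ = float(np.log(10.0) / self.b_)
        else:
            self.etr_max_ = None
            self.ppfd_sat_ = None
        return self

    def predict(self, X):
        return self._model()(np.asarray(X, dtype=float).reshape(-1), self.a_, self.b_)


_DEFAULT_FORMS = {"etr": "rise_to_max", "yield": "exp_decay"}
# the literal reading of some conventions swaps the two printed formulas
_LITERAL_FORMS = {"etr": "exp_decay", "yield": "rise_to_max"}


def fit_light_curve(
    curve: LightCurve | tuple,
    target: str = "etr",
    form: str | None = None,
    max_restarts: int = 5,
    random_state: int | None = 0,
) -> CurveFit:
    """Fit a light-response curve for one target quantity.

    ``target='etr'`` converts yields to ETR and fits the rise-to-max model
    (ETRmax = a, PPFDsat = ln(10)/b); ``target='yield'`` fits the decay
    model to dF/Fm' directly. ``form`` overrides the model: one of
    'rise_to_max', 'exp_decay' or 'literal' (the swapped-formula reading).
    """
    if target not in ("etr", "yield"):
        raise ValueError("target must be 'etr' or 'yield'")
    if isinstance(curve, LightCurve):
        x, yld = curve.ppfd, curve.yields
    else:
        x, yld = (np.asarray(v, dtype=float) for v in curve)
    y = etr(yld, x) if target == "etr" else yld
    if form is None:
        form = _DEFAULT_FORMS[target]
    elif form == "literal":
        form = _LITERAL_FORMS[target]
    est = LightResponseRegression(
        form=form, max_restarts=max_restarts, random_state=random_state
    ).fit(x, y)
    fit = CurveFit(
        target=target,
        form=form,
        a=est.a_,
        b=est.b_,
        rss=est.rss_,
        n_points=est.n_points_,
        converged=est.converged_,
        etr_max=est.etr_max_,
        ppfd_sat=est.ppfd_sat_,
    )
    return fit


def fit_curve_pair(curve: LightCurve, random_state: int | None = 0):
    """Fit both targets and evaluate dF/Fm' at PPFDsat.

    Returns (etr_fit, yield_fit); ``etr_fit.yield_at_sat`` is the fitted
    yield model evaluated at the ETR saturation point.
    """
    etr_fit = fit_light_curve(curve, "etr", random_state=random_state)
    yield_fit = fit_light_curve(curve, "yield", random_state=random_state)
    if etr_fit.converged and yield_fit.converged and etr_fit.ppfd_sat is not None:
        at_sat = float(yield_fit.predict(etr_fit.ppfd_sat))
        etr_fit.yield_at_sat = at_sat
        yield_fit.yield_at_sat = at_sat
        yield_fit.ppfd_sat = etr_fit.ppfd_sat
    return etr_fit, yield_fit
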