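"""Significance-filtered random-forest driver screen.

Identifies which of a large, mutually correlated set of plot covariates
(urban parameters at several buffer radii, soil, climate, biodiversity)
drive an ecosystem-functioning proxy. A random-forest regressor is fitted,
permutation importance is averaged over many re-randomizations, each
predictor's averaged importance is tested against a permutation null
(response permutation by default), non-significant importances are set to
zero, and the surviving importances are converted to shares of the model's
explanatory R^2. Partial-dependence curves give effect directions.

The permutation (not impurity) importance of a plain random forest stands
in for a conditional-inference forest: it is the importance notion that
remains approximately unbiased among correlated predictors.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.ensemble import RandomForestRegressor
from sklearn.metrics import r2_score
from sklearn.model_selection import KFold
from sklearn.utils import check_random_state

__all__ = [
    "DriverScreenConfig",
    "DriverScreen",
    "fit_forest",
    "mean_importance",
    "permutation_pvalues",
    "r2_contribution",
    "buffer_group_importance",
    "partial_dependence",
]


@dataclass
class DriverScreenConfig:
    """Screen settings; defaults match the full-fidelity protocol
    (2000 trees, 100 importance repeats, 999 permutations, alpha 0.05)."""

    n_trees: int = 2000
    n_importance_repeats: int = 100
    n_permutations: int = 999
    alpha: float = 0.05
    cv_folds: int = 5
    null_mode: str = "response"
    n_null_repeats: int | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")
        if self.null_mode not in ("response", "predictor"):
            raise ValueError("null_mode must be 'response' or 'predictor'")


class DriverScreen(BaseEstimator):
    """Random-forest driver screen as a scikit-learn estimator.

    Parameters mirror :class:`DriverScreenConfig`. Missing predictor values
    are median-imputed (within training folds for validation).

    Attributes (after ``fit``)
    --------------------------
    raw_importances_ : mean permutation importance per predictor.
    pvalues_ : permutation p-values, (1 + #{null >= obs}) / (n_perm + 1).
    significant_ : boolean mask, p <= alpha.
    importances_ : raw importances with non-significant entries set to 0.
    r2_contributions_ : per-predictor share of explanatory R^2, in percent;
        significant shares sum to model_r2_ * 100.
    model_r2_ : explanatory R^2 on the training data.
    validation_r2_ : mean k-fold cross-validated R^2.
    """

    def __init__(
        self,
        n_trees: int = 2000,
        n_importance_repeats: int = 100,
        n_permutations: int = 999,
        alpha: float = 0.05,
        cv_folds: int = 5,
        null_mode: str = "response",
        n_null_repeats: int | None = None,
        random_state: int | None = None,
    ):
        self.n_trees = n_trees
        self.n_importance_repeats = n_importance_repeats
        self.n_permutations = n_permutations
        self.alpha = alpha
        self.cv_folds = cv_folds
        self.null_mode = null_mode
        self.n_null_repeats = n_null_repeats
        self.random_state = random_state

    # -- helpers ---------------------------------------------------------
    def _validate(self, X, y):
        if isinstance(X, pd.DataFrame):
            names = [str(c) for c in X.columns]
            Xv = X.to_numpy(dtype=float)
        else:
            Xv = np.asarray(X, dtype=float)
            names = [f"x{j}" for j in range(Xv.shape[1])]
        yv = np.asarray(y, dtype=float).reshape(-1)
        if Xv.ndim != 2 or Xv.shape[0] != len(yv):
            raise ValueError("X and y shapes do not align")
        if Xv.shape[0] < 10:
            raise ValueError("need at least 10 samples")
        if np.ptp(yv) == 0:
            raise ValueError("constant response")
        return Xv, yv, names

    def _impute(self, X, medians=None):
        if medians is None:
            medians = np.nanmedian(X, axis=0)
            medians = np.where(np.isfinite(medians), medians, 0.0)
        out = X.copy()
        idx = np.where(np.isnan(out))
        out[idx] = np.take(medians, idx[1])
        return out, medians

    def _forest(self, seed):
        return RandomForestRegressor(
            n_estimators=self.n_trees, random_state=seed, n_jobs=1
        )

    def _mean_importance(self, forest, X, y, seed, n_repeats):
        # permutation importance (loss in R^2 when one column is shuffled),
        # averaged over seed-varied repeats; all column shuffles of all
        # repeats are scored with a single stacked predict call
        n, p = X.shape
        rng = np.random.default_rng(seed)
        blocks = np.empty((1 + n_repeats * p, n, p))
        blocks[0] = X
        k = 1
        for _ in range(n_repeats):
            for j in range(p):
                Xp = X.copy()
                Xp[:, j] = X[rng.permutation(n), j]
                blocks[k] = Xp
                k += 1
        preds = forest.predict(blocks.reshape(-1, p)).reshape(len(blocks), n)
        sst = float(((y - y.mean()) ** 2).sum())
        sse = ((preds - y[None, :]) ** 2).sum(axis=1)
        r2 = 1.0 - sse / sst
        drops = r2[0] - r2[1:].reshape(n_repeats, p)
        return drops.mean(axis=0)

    # -- fit -------------------------------------------------------------
    def fit(self, X, y):
        Xv, yv, names = self._validate(X, y)
        self.feature_names_in_ = np.asarray(names, dtype=object)
        rng = check_random_state(self.random_state)
        seeds = rng.randint(0, 2**31 - 1, size=5)
        n_null = self.n_null_repeats or self.n_importance_repeats

        Xi, medians = self._impute(Xv)
        self._medians_ = medians
        self._X_train_ = Xi
        forest = self._forest(int(seeds[0])).fit(Xi, yv)
        self.forest_ = forest
        self.model_r2_ = float(forest.score(Xi, yv))

        # validation R^2 by k-fold CV with within-fold imputation
        folds = KFold(n_splits=min(self.cv_folds, len(yv)), shuffle=True,
                      random_state=int(seeds[1]))
        fold_r2 = []
        for tr, te in folds.split(Xi):
            Xtr, med = self._impute(Xv[tr])
            Xte, _ = self._impute(Xv[te], med)
            f = self._forest(int(seeds[0])).fit(Xtr, yv[tr])
            fold_r2.append(r2_score(yv[te], f.predict(Xte)))
        self.validation_r2_ = float(np.mean(fold_r2))

        obs = self._mean_importance(
            forest, Xi, yv, int(seeds[2]), self.n_importance_repeats
        )
        self.raw_importances_ = obs

        perm_rng = np.random.default_rng(int(seeds[3]))
        exceed = np.zeros(len(names), dtype=int)
        if self.null_mode == "response":
            for k in range(self.n_permutations):
                yp = perm_rng.permutation(yv)
                f = self._forest(int(seeds[0])).fit(Xi, yp)
                null = self._mean_importance(f, Xi, yp, int(seeds[2]), n_null)
                exceed += null >= obs
        else:  # per-predictor null: permute one column at a time
            for j in range(len(names)):
                for k in range(self.n_permutations):
                    Xp = Xi.copy()
                    Xp[:, j] = perm_rng.permutation(Xp[:, j])
                    f = self._forest(int(seeds[0])).fit(Xp, yv)
                    null_j = self._mean_importance(
                        f, Xp, yv, int(seeds[2]), n_null
                    )[j]
                    exceed[j] += null_j >= obs[j]

        self.pvalues_ = (1.0 + exceed) / (self.n_permutations + 1.0)
        self.significant_ = self.pvalues_ <= self.alpha
        self.importances_ = np.where(self.significant_, obs, 0.0)
        self.r2_contributions_ = r2_contribution(
            self.importances_, self.model_r2_, allow_all_zero=True
        )
        return self

    def predict(self, X):
        Xv = np.asarray(X, dtype=float)
        Xi, _ = self._impute(Xv, self._medians_)
        return self.forest_.predict(Xi)

    # -- reporting -------------------------------------------------------
    def result_frame(self) -> pd.DataFrame:
        """Tidy per-predictor result table."""
        return pd.DataFrame(
            {
                "predictor": self.feature_names_in_,
                "mean_importance": self.raw_importances_,
                "p_value": self.pvalues_,
                "significant": self.significant_,
                "importance": self.importances_,
                "r2_contribution_pct": self.r2_contributions_,
            }
        )

    def partial_dependence(self, predictor, X=None, grid_size: int = 20,
                           normalize: bool = True):
        names = list(self.feature_names_in_)
        j = names.index(predictor) if isinstance(predictor, str) else int(predictor)
        Xi = self._X_train_ if X is None else self._impute(
            np.asarray(X, dtype=float), self._medians_)[0]
        return partial_dependence(self.forest_, Xi, j, grid_size, normalize)


# ---------------------------------------------------------------------------
# functional surface


def _screen(config: DriverScreenConfig | None) -> DriverScreen:
    cfg = config or DriverScreenConfig()
    return DriverScreen(
        n_trees=cfg.n_trees,
        n_importance_repeats=cfg.n_importance_repeats,
        n_permutations=cfg.n_permutations,
        alpha=cfg.alpha,
        cv_folds=cfg.cv_folds,
        null_mode=cfg.null_mode,
        n_null_repeats=cfg.n_null_repeats,
        random_state=cfg.seed,
    )


def fit_forest(X, y, config: DriverScreenConfig | None = None):
    """Fit the ensemble; returns (model, explanatory R^2, validation R^2)."""
    scr = _screen(config)
    Xv, yv, _ = scr._validate(X, y)
    rng = check_random_state(scr.random_state)
    seeds = rng.randint(0, 2**31 - 1, size=2)
    Xi, medians = scr._impute(Xv)
    forest = scr._forest(int(seeds[0])).fit(Xi, yv)
    model_r2 = float(forest.score(Xi, yv))
    folds = KFold(n_splits=min(scr.cv_folds, len(yv)), shuffle=True,
                  random_state=int(seeds[1]))
    fold_r2 = []
    for tr, te in folds.split(Xi):
        Xtr, med = scr._impute(Xv[tr])
        Xte, _ = scr._impute(Xv[te], med)
        f = scr._forest(int(seeds[0])).fit(Xtr, yv[tr])
        fold_r2.append(r2_score(yv[te], f.predict(Xte)))
    return forest, model_r2, float(np.mean(fold_r2))


def mean_importance(X, y, config: DriverScreenConfig | None = None) -> np.ndarray:
    """Permutation importance averaged over seed-varied repeats."""
    scr = _screen(config)
    Xv, yv, _ = scr._validate(X, y)
    rng = check_random_state(scr.random_state)
    seeds = rng.randint(0, 2**31 - 1, size=3)
    Xi, _ = scr._impute(Xv)
    forest = scr._forest(int(seeds[0])).fit(Xi, yv)
    return scr._mean_importance(forest, Xi, yv, int(seeds[2]),
                                scr.n_importance_repeats)


def permutation_pvalues(X, y, observed, config: DriverScreenConfig | None = None):
    """Permutation p-values and significance flags for observed importances.

    Re-computes the averaged importance ``config.n_permutations`` times
    under a permuted response (or permuted predictor, per ``null_mode``);
    p = (1 + #{null >= observed}) / (n_permutations + 1); importances of
    non-significant predictors are zeroed.
    Returns (pvalues, significant, zeroed_importances).
    """
    scr = _screen(config)
    Xv, yv, _ = scr._validate(X, y)
    obs = np.asarray(observed, dtype=float)
    if len(obs) != Xv.shape[1]:
        raise ValueError("observed importances do not match X")
    rng = check_random_state(scr.random_state)
    seeds = rng.randint(0, 2**31 - 1, size=5)
    n_null = scr.n_null_repeats or scr.n_importance_repeats
    Xi, _ = scr._impute(Xv)
    perm_rng = np.random.default_rng(int(seeds[3]))
    exceed = np.zeros(len(obs), dtype=int)
    if scr.null_mode == "response":
        for _ in range(scr.n_permutations):
            yp = perm_rng.permutation(yv)
            f = scr._forest(int(seeds[0])).fit(Xi, yp)
            null = scr._mean_importance(f, Xi, yp, int(seeds[2]), n_null)
            exceed += null >= obs
    else:
        for j in range(len(obs)):
            for _ in range(scr.n_permutations):
                Xp = Xi.copy()
                Xp[:, j] = perm_rng.permutation(Xp[:, j])
                f = scr._forest(int(seeds[0])).fit(Xp, yv)
                null_j = scr._mean_importance(f, Xp, yv, int(seeds[2]), n_null)[j]
                exceed[j] += null_j >= obs[j]
    p = (1.0 + exceed) / (scr.n_permutations + 1.0)
    sig = p <= scr.alpha
    return p, sig, np.where(sig, obs, 0.0)


def r2_contribution(importances, model_r2: float, allow_all_zero: bool = False):
    """Convert importances to percent shares of the model's R^2.

    share_k = importance_k / sum(importances) * model_r2 * 100; zero
    importances stay exactly zero.
    """
    imp = np.asarray(importances, dtype=float)
    total = imp.sum()
    if total <= 0:
        if allow_all_zero:
            return np.zeros_like(imp)
        raise ValueError("undefined share: no positive importance")
    return imp / total * model_r2 * 100.0


def buffer_group_importance(
    shares: pd.Series | Mapping[str, float],
    groups: Mapping[str, Sequence[str]],
) -> pd.Series:
    """Sum R^2 shares over named predictor families (e.g. buffer radii).

    Families must not overlap; predictors outside every family are reported
    individually. The grand total is conserved.
    """
    s = pd.Series(shares, dtype=float)
    seen: set = set()
    for name, members in groups.items():
        members = list(members)
        overlap = seen & set(members)
        if overlap:
            raise ValueError(f"overlapping families at {sorted(overlap)}")
        missing = set(members) - set(s.index)
        if missing:
            raise KeyError(f"unknown predictors in family {name}: {sorted(missing)}")
        seen |= set(members)
    out = {}
    for name, members in groups.items():
        out[name] = float(s.loc[list(members)].sum())
    for pred in s.index:
        if pred not in seen:
            out[pred] = float(s.loc[pred])
    return pd.Series(out)


def partial_dependence(model, X, predictor, grid_size: int = 20,
                       normalize: bool = True):
    """Partial-dependence curve of a fitted regressor for one predictor.

    For each grid value g (an even grid from the predictor's min to max),
    the predictor column is set to g for every row and predictions are
    averaged, marginalizing the remaining predictors. With ``normalize``
    the response is min-max scaled to [0, 1], so curves show effect
    direction, not effect size. Returns (grid, response).
    """
    if isinstance(X, pd.DataFrame):
        j = list(X.columns).index(predictor) if isinstance(predictor, str) else int(predictor)
        Xv = X.to_numpy(dtype=float)
    else:
        Xv = np.asarray(X, dtype=float)
        j = int(predictor)
    lo, hi = float(np.nanmin(Xv[:, j])), float(np.nanmax(Xv[:, j]))
    if hi <= lo:
        raise ValueError("degenerate grid: constant predictor")
    grid = np.linspace(lo, hi, grid_size)
    resp = np.empty(grid_size)
    work = Xv.copy()
    for k, g in enumerate(grid):
        work[:, j] = g
        resp[k] = float(np.mean(model.predict(work)))
    if normalize:
        span = resp.max() - resp.min()
        resp = (resp - resp.min()) / span if span > 0 else np.zeros_like(resp)
    return grid, resp
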