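"""Statistical battery: correlations, agreement, group comparison, model fit.

Spearman correlations carry a qualitative strength label by |rho| band:
[0, 0.20) very weak, [0.20, 0.40) weak, [0.40, 0.60) moderate,
[0.60, 0.80) strong, [0.80, 1] very strong.  For n <= 9 the Spearman p-value
is the exhaustive two-sided permutation tail; beyond that the usual
t-approximation is used.

Lin's concordance correlation coefficient (CCC) measures absolute agreement:
ccc = 2 cov(x, y) / (var x + var y + (mean x - mean y)^2), population (1/n)
moments, penalizing location/scale shift on top of correlation loss.

Model selection is bidirectional stepwise search on a Gaussian linear model
scored by AIC, starting from the intercept-only model; predictive value is
assessed by k-fold cross-validation with the selection re-run inside every
training split, reported as the Pearson r of out-of-fold predictions against
the observed target.
"""
from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

from .errors import (
    FoldError,
    InsufficientDataError,
    UndefinedCorrelationError,
)

log = logging.getLogger(__name__)

STRENGTH_BANDS = (
    (0.20, "very_weak"),
    (0.40, "weak"),
    (0.60, "moderate"),
    (0.80, "strong"),
    (np.inf, "very_strong"),
)


def strength_label(rho: float) -> str:
    a = abs(rho)
    for upper, name in STRENGTH_BANDS:
        if a < upper or upper is np.inf:
            return name
    return "very_strong"


@dataclass
class CorrelationResult:
    rho: float
    p_value: float
    strength: str
    n: int


@dataclass
class GroupComparison:
    means: list[float]
    sds: list[float]
    ns: list[int]
    f_statistic: float
    anova_p: float
    tukey: dict[tuple[int, int], float]  # pairwise adjusted p-values


@dataclass
class ModelFit:
    selected_features: list[str]
    coefficients: dict[str, float]  # includes "intercept"
    aic: float
    cv_predictions: np.ndarray | None = None
    in_fold_r: float | None = None
    out_of_fold_r: float | None = None
    n: int = 0
    dropped_rows: int = 0
    history: list[tuple[str, str, float]] = field(default_factory=list)


def _check_pair(x, y, min_n):
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1D vectors")
    if x.size < min_n:
        raise ValueError(f"need at least {min_n} observations, got {x.size}")
    return x, y


def _spearman_exact_p(xr: np.ndarray, yr: np.ndarray, rho_obs: float) -> float:
    """Two-sided tail over all n! permutations of one rank vector."""
    n = xr.size
    perms = np.array(list(itertools.permutations(range(n))), dtype=np.int64)
    xc = xr - xr.mean()
    yc = yr - yr.mean()
    denom = np.sqrt((xc**2).sum() * (yc**2).sum())
    rhos = (yc[perms] @ xc) / denom
    return float(np.mean(np.abs(rhos) >= abs(rho_obs) - 1e-12))


def spearman(x, y) -> CorrelationResult:
    """Rank correlation with strength band; exact permutation p for n <= 9."""
    x, y = _check_pair(x, y, 3)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedCorrelationError("constant input vector")
    xr = sps.rankdata(x)
    yr = sps.rankdata(y)
    rho = float(np.corrcoef(xr, yr)[0, 1])
    n = x.size
    if n <= 9:
        p = _spearman_exact_p(xr, yr, rho)
    elif abs(rho) >= 1.0:
        p = 0.0
    else:
        t = rho * np.sqrt((n - 2) / (1 - rho**2))
        p = float(2 * sps.t.sf(abs(t), n - 2))
    return CorrelationResult(rho=rho, p_value=p, strength=strength_label(rho), n=n)


def pearson(x, y) -> CorrelationResult:
    x, y = _check_pair(x, y, 3)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedCorrelationError("constant input vector")
    r, p = sps.pearsonr(x, y)
    return CorrelationResult(
        rho=float(r), p_value=float(p), strength=strength_label(r), n=x.size
    )


def lin_ccc(x, y) -> float:
    """Lin's concordance correlation coefficient (population moments)."""
    x, y = _check_pair(x, y, 2)
    vx = float(np.var(x))
    vy = float(np.var(y))
    dm = float(np.mean(x) - np.mean(y))
    denom = vx + vy + dm**2
    if denom == 0.0:
        return 1.0  # both constant and equal: perfect agreement
    cov = float(np.mean((x - x.mean()) * (y - y.mean())))
    return 2.0 * cov / denom


def anova_tukey(groups: list) -> GroupComparison:
    """One-way fixed-effects ANOVA with Tukey(-Kramer) HSD post hoc."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    for g in groups:
        if g.size < 2:
            raise ValueError("each group needs n >= 2")
    means = [float(g.mean()) for g in groups]
    sds = [float(g.std(ddof=1)) for g in groups]
    ns = [int(g.size) for g in groups]
    allv = np.concatenate(groups)
    k = len(groups)
    if np.ptp(allv) == 0:
        tukey = {(a, b): 1.0 for a in range(k) for b in range(a + 1, k)}
        return GroupComparison(means, sds, ns, 0.0, 1.0, tukey)
    f, p = sps.f_oneway(*groups)
    hsd = sps.tukey_hsd(*groups)
    tukey = {
        (a, b): float(hsd.pvalue[a, b]) for a in range(k) for b in range(a + 1, k)
    }
    return GroupComparison(means, sds, ns, float(f), float(p), tukey)


def _ols_aic(y: np.ndarray, X: pd.DataFrame, cols: list[str]):
    design = sm.add_constant(X[cols], has_constant="add") if cols else pd.DataFrame(
        {"const": np.ones(len(y))}, index=X.index
    )
    res = sm.OLS(y, design).fit()
    return float(res.aic), res


def stepwise_aic_fit(features: pd.DataFrame, target) -> ModelFit:
    """Bidirectional stepwise OLS selection by AIC from the intercept-only model.

    At each step the single add-or-drop move with the lowest AIC is taken
    (ties broken by candidate order: additions in column order first, then
    drops), stopping at a local AIC minimum.  Rows with missing values are
    dropped and logged.
    """
    y = pd.Series(np.asarray(target, dtype=float), index=features.index)
    data = features.assign(__target=y)
    complete = data.dropna()
    dropped = len(data) - len(complete)
    if dropped:
        log.info("stepwise fit dropped %d incomplete rows", dropped)
    if len(complete) < 3:
        raise InsufficientDataError(
            f"only {len(complete)} complete rows; need at least 3"
        )
    yv = complete["__target"].to_numpy()
    X = complete.drop(columns="__target")
    cols = list(X.columns)

    selected: list[str] = []
    current_aic, current_res = _ols_aic(yv, X, selected)
    history: list[tuple[str, str, float]] = [("start", "", current_aic)]
    while True:
        best = None  # (aic, action, feature)
        for f in cols:
            if f in selected and len(selected) > 0:
                trial = [c for c in selected if c != f]
                action = "drop"
            elif f not in selected:
                trial = selected + [f]
                action = "add"
            else:
                continue
            if len(trial) + 2 > len(complete):
                continue  # keep the model estimable
            aic, _ = _ols_aic(yv, X, trial)
            if best is None or aic < best[0] - 1e-10:
                best = (aic, action, f, trial)
        if best is None or best[0] >= current_aic - 1e-10:
            break
        current_aic, action, feat, selected = best[0], best[1], best[2], best[3]
        history.append((action, feat, current_aic))
    _, res = _ols_aic(yv, X, selected)
    coefs = {"intercept": float(res.params.get("const", 0.0))}
    for f in selected:
        coefs[f] = float(res.params[f])
    return ModelFit(
        selected_features=selected,
        coefficients=coefs,
        aic=current_aic,
        n=len(complete),
        dropped_rows=dropped,
        history=history,
    )


def _predict(fit: ModelFit, X: pd.DataFrame) -> np.ndarray:
    pred = np.full(len(X), fit.coefficients["intercept"], dtype=float)
    for f in fit.selected_features:
        pred += fit.coefficients[f] * X[f].to_numpy(dtype=float)
    return pred


def cross_validated_prediction(
    features: pd.DataFrame, target, k: int = 10, seed: int = 0
) -> ModelFit:
    """k-fold CV of the stepwise model; selection re-run per training split.

    Returns a ModelFit for the full data, with ``cv_predictions`` holding
    out-of-fold predictions (aligned to ``features``), ``out_of_fold_r`` the
    Pearson r of those against the observed target, and ``in_fold_r`` the
    Pearson r of full-data fitted values.
    """
    y = np.asarray(target, dtype=float)
    n = len(features)
    if k > n:
        raise FoldError(f"k={k} folds exceed n={n} observations")
    full = stepwise_aic_fit(features, y)
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    folds = np.array_split(order, k)
    preds = np.full(n, np.nan)
    for fold in folds:
        train = np.setdiff1d(order, fold)
        fit = stepwise_aic_fit(features.iloc[train], y[train])
        preds[fold] = _predict(fit, features.iloc[fold])
    full.cv_predictions = preds
    full.out_of_fold_r = _safe_r(preds, y)
    full.in_fold_r = _safe_r(_predict(full, features), y)
    return full


def _safe_r(a: np.ndarray, b: np.ndarray) -> float:
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        return float("nan")
    return float(np.corrcoef(a, b)[0, 1])
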