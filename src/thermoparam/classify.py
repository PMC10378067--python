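"""NED-vs-active melanoma classification by logistic regression.

The clinical question: given a melanoma patient's demographics and
thermogram parameters, how probable is active disease versus no evidence of
disease (NED)?  Controls are excluded before any of this.

Workflow pieces, usable separately or through :class:`NedActiveLogit`:

* ``vif_reduce`` — iterative variance-inflation-factor screening of the
  thermogram predictors (drop the worst offender until all VIF <= 5,
  i.e. no more than ~80% multicollinearity);
* ``stepwise_select`` — greedy forward/backward selection under AIC or BIC
  (a step is accepted only if the criterion strictly decreases, so ties
  keep the smaller model);
* ``cross_validate`` — 25 repeats of stratified 5-fold cross-validation,
  scoring held-out ROC-AUC plus threshold-0.5 confusion metrics and an
  empirical ROC band;
* ``predict_probability`` / ``odds_interpretation`` — inverse-logit
  predictions with delta-method CIs, and the per-unit percentage change in
  odds, 100·(exp(beta) − 1).

``calibrate_intercept`` solves for the intercept that makes a model with
fixed slopes reproduce a stated probability at reference covariates; this
supports worked examples quoted from coefficient tables, where the
intercept itself is not printed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.special import expit, logit
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold

__all__ = [
    "LogisticModel",
    "CVReport",
    "NedActiveLogit",
    "MODEL_SPECS",
    "vif_reduce",
    "stepwise_select",
    "cross_validate",
    "predict_probability",
    "odds_interpretation",
    "calibrate_intercept",
    "prepare_classification_table",
]

#: Published candidate model specifications (predictor sets).
MODEL_SPECS: dict[int, tuple[str, ...]] = {
    1: ("age",),
    2: ("age", "TPeak2"),
    3: ("TPeak2",),
    4: ("age", "Width", "TPeak1", "TPeak2", "Peak2.3", "PC4"),
}


@dataclass
class LogisticModel:
    """A fitted (or externally specified) binary logistic model."""

    predictors: list[str]
    coefficients: np.ndarray            # slope per predictor (log-odds / unit)
    intercept: float
    se: np.ndarray | None = None        # slope standard errors
    cov: np.ndarray | None = None       # covariance of (intercept, slopes)
    llf: float | None = None
    aic: float | None = None
    bic: float | None = None
    n: int | None = None
    penalized: bool = False

    def __post_init__(self) -> None:
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        if not np.all(np.isfinite(self.coefficients)) or not np.isfinite(self.intercept):
            raise ValueError("logistic coefficients must be finite")
        if len(self.predictors) != self.coefficients.size:
            raise ValueError("one coefficient per predictor required")

    def linear_predictor(self, covariates: Mapping[str, float]) -> float:
        missing = [p for p in self.predictors if p not in covariates]
        if missing:
            raise KeyError(f"missing covariates: {missing}")
        x = np.array([covariates[p] for p in self.predictors], dtype=float)
        return float(self.intercept + x @ self.coefficients)

    def summary(self) -> pd.DataFrame:
        rows = [{"term": "Intercept", "estimate": self.intercept,
                 "se": np.nan, "odds_change_pct": np.nan}]
        for i, name in enumerate(self.predictors):
            rows.append({
                "term": name,
                "estimate": float(self.coefficients[i]),
                "se": float(self.se[i]) if self.se is not None else np.nan,
                "odds_change_pct": odds_interpretation(self.coefficients[i]),
            })
        return pd.DataFrame(rows)


def odds_interpretation(coefficient: float) -> float:
    """Percent change in odds per unit covariate, 100·(exp(beta) − 1),
    reported to one decimal."""
    if not np.isfinite(coefficient):
        raise ValueError("coefficient must be finite")
    return round(100.0 * (np.exp(coefficient) - 1.0), 1)


def calibrate_intercept(
    coefficients: Mapping[str, float],
    covariates: Mapping[str, float],
    probability: float,
) -> float:
    """Intercept making ``probability`` the prediction at ``covariates``
    under the given slopes."""
    if not 0 < probability < 1:
        raise ValueError("probability must be in (0, 1)")
    lp = sum(coefficients[k] * covariates[k] for k in coefficients)
    return float(logit(probability) - lp)


def predict_probability(
    model: LogisticModel, covariates: Mapping[str, float], ci_level: float = 0.95
) -> tuple[float, tuple[float, float] | None]:
    """Inverse-logit prediction; delta-method CI on the logit scale when the
    model carries a covariance matrix."""
    lp = model.linear_predictor(covariates)
    prob = float(expit(lp))
    if model.cov is None:
        return prob, None
    x = np.concatenate(([1.0], [covariates[p] for p in model.predictors]))
    var = float(x @ model.cov @ x)
    from scipy.stats import norm

    zq = norm.ppf(0.5 + ci_level / 2.0)
    half = zq * np.sqrt(max(var, 0.0))
    return prob, (float(expit(lp - half)), float(expit(lp + half)))


# ---------------------------------------------------------------------------
# Multicollinearity screening
# ---------------------------------------------------------------------------

def _vif(X: np.ndarray, j: int) -> float:
    """VIF of column j: 1 / (1 − R²) regressing it on the other columns."""
    y = X[:, j]
    others = np.delete(X, j, axis=1)
    others = np.column_stack([np.ones(X.shape[0]), others])
    beta, _, _, _ = np.linalg.lstsq(others, y, rcond=None)
    resid = y - others @ beta
    tss = np.sum((y - y.mean()) ** 2)
    if tss <= 0:
        raise ValueError("constant predictor column")
    r2 = 1.0 - np.sum(resid**2) / tss
    if r2 >= 1.0 - 1e-12:
        return np.inf
    return 1.0 / (1.0 - r2)


def vif_reduce(design: pd.DataFrame, threshold: float = 5.0) -> list[str]:
    """Iteratively drop the highest-VIF predictor until all VIF <= threshold.

    Deterministic: among (numerically) tied maxima the later column is
    dropped, so perfectly collinear pairs lose their later member.
    """
    if design.shape[1] < 2:
        return list(design.columns)
    cols = list(design.columns)
    X = design.to_numpy(dtype=float)
    if np.any(np.std(X, axis=0) == 0):
        bad = [c for c, s in zip(cols, np.std(X, axis=0)) if s == 0]
        raise ValueError(f"constant predictor columns: {bad}")
    while len(cols) > 1:
        vifs = np.array([_vif(X, j) for j in range(len(cols))])
        vmax = vifs.max()
        if vmax <= threshold:
            break
        ties = np.flatnonzero(
            np.isclose(vifs, vmax, rtol=1e-12, atol=0) | (np.isinf(vifs) & np.isinf(vmax))
        )
        drop = int(ties[-1])
        if np.isinf(vmax):
            warnings.warn(
                f"perfectly collinear predictor {cols[drop]!r} dropped", stacklevel=2
            )
        del cols[drop]
        X = np.delete(X, drop, axis=1)
    return cols


# ---------------------------------------------------------------------------
# Fitting and stepwise selection
# ---------------------------------------------------------------------------

def _fit_logit(X: pd.DataFrame, y: np.ndarray, predictors: Sequence[str]) -> LogisticModel:
    n = len(y)
    design = np.column_stack(
        [np.ones(n)] + [X[p].to_numpy(dtype=float) for p in predictors]
    )
    penalized = False
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.Logit(y, design).fit(disp=0, maxiter=200)
            ok = np.all(np.isfinite(res.params)) and np.all(
                np.abs(res.params) < 1e3
            )
        except Exception:
            ok = False
    if ok:
        params = np.asarray(res.params)
        cov = np.asarray(res.cov_params())
        se = np.sqrt(np.diag(cov))[1:]
        return LogisticModel(
            list(predictors), params[1:], float(params[0]), se=se, cov=cov,
            llf=float(res.llf), aic=float(res.aic), bic=float(res.bic), n=n,
        )
    # separation / divergence: ridge-penalized fallback
    warnings.warn("separation detected; using penalized logistic fallback", stacklevel=2)
    penalized = True
    from sklearn.linear_model import LogisticRegression

    lr = LogisticRegression(C=1e2, max_iter=2000)
    lr.fit(design[:, 1:] if len(predictors) else np.zeros((n, 1)), y)
    coef = lr.coef_.ravel() if len(predictors) else np.array([])
    intercept = float(lr.intercept_[0])
    lp = intercept + (design[:, 1:] @ coef if len(predictors) else 0.0)
    p = expit(lp)
    eps = 1e-12
    llf = float(np.sum(y * np.log(p + eps) + (1 - y) * np.log(1 - p + eps)))
    k = len(predictors) + 1
    return LogisticModel(
        list(predictors), coef, intercept, llf=llf,
        aic=2 * k - 2 * llf, bic=k * np.log(n) - 2 * llf, n=n, penalized=penalized,
    )


def _criterion(model: LogisticModel, criterion: str) -> float:
    return model.aic if criterion == "AIC" else model.bic  # type: ignore[return-value]


def stepwise_select(
    X: pd.DataFrame,
    y: Sequence[int],
    candidates: Sequence[str] | None = None,
    direction: str = "forward",
    criterion: str = "AIC",
) -> LogisticModel:
    """Greedy stepwise logistic selection under AIC or BIC.

    Forward starts at intercept-only and adds the candidate with the best
    criterion improvement; backward starts at the full candidate set and
    removes.  Steps are accepted only if the criterion strictly decreases;
    candidate order breaks ties, so the result is deterministic.
    """
    if direction not in ("forward", "backward"):
        raise ValueError("direction must be 'forward' or 'backward'")
    if criterion not in ("AIC", "BIC"):
        raise ValueError("criterion must be 'AIC' or 'BIC'")
    y = np.asarray(y, dtype=float)
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("response must be binary 0/1")
    candidates = list(candidates if candidates is not None else X.columns)
    current = [] if direction == "forward" else list(candidates)
    best = _fit_logit(X, y, current)
    best_crit = _criterion(best, criterion)
    improved = True
    while improved:
        improved = False
        if direction == "forward":
            moves = [current + [c] for c in candidates if c not in current]
        else:
            moves = [[c for c in current if c != drop] for drop in current]
        for move in moves:
            cand = _fit_logit(X, y, move)
            crit = _criterion(cand, criterion)
            if crit < best_crit - 1e-10:
                best, best_crit, current = cand, crit, move
                improved = True
    return best


# ---------------------------------------------------------------------------
# Repeated stratified cross-validation
# ---------------------------------------------------------------------------

@dataclass
class CVReport:
    """Repeated stratified CV performance of one model specification."""

    predictors: list[str]
    repeats: int
    folds: int
    seed: int
    aucs: np.ndarray                     # (repeats * folds,)
    accuracy: float
    sensitivity: float
    specificity: float
    balanced_accuracy: float
    roc_grid: np.ndarray                 # common FPR grid
    roc_mean: np.ndarray
    roc_band: tuple[np.ndarray, np.ndarray]
    seed_schedule: list[int] = field(default_factory=list)

    @property
    def mean_auc(self) -> float:
        return float(self.aucs.mean())

    def as_dict(self) -> dict:
        return {
            "predictors": self.predictors,
            "repeats": self.repeats,
            "folds": self.folds,
            "seed": self.seed,
            "seed_schedule": self.seed_schedule,
            "mean_auc": self.mean_auc,
            "auc_sd": float(self.aucs.std(ddof=1)),
            "accuracy": self.accuracy,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "balanced_accuracy": self.balanced_accuracy,
        }


def cross_validate(
    data: pd.DataFrame,
    predictors: Sequence[str],
    y: Sequence[int],
    repeats: int = 25,
    folds: int = 5,
    seed: int = 0,
    threshold: float = 0.5,
) -> CVReport:
    """25×5 (by default) repeated stratified cross-validation.

    Rows are sorted by index before partitioning, so the report is invariant
    to input sample order.  Repeat ``r`` shuffles with seed ``seed + r``
    (recorded in the report).  A partition yielding a single-class fold is
    re-randomized with a shifted seed and logged.
    """
    y = np.asarray(y, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    order = np.argsort(data.index.to_numpy())
    data = data.iloc[order]
    y = y[order]
    aucs: list[float] = []
    schedule: list[int] = []
    grid = np.linspace(0.0, 1.0, 101)
    rocs: list[np.ndarray] = []
    pooled_pred = np.full(len(y) * repeats, np.nan)
    pooled_true = np.full(len(y) * repeats, -1)
    pos = 0
    for r in range(repeats):
        fold_seed = seed + r
        for _attempt in range(10):
            skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=fold_seed)
            splits = list(skf.split(np.zeros(len(y)), y))
            if all(len(np.unique(y[te])) == 2 and len(np.unique(y[tr])) == 2 for tr, te in splits):
                break
            warnings.warn(f"single-class fold at repeat {r}; re-randomizing", stacklevel=2)
            fold_seed += 1000 * repeats
        schedule.append(fold_seed)
        for train, test in splits:
            model = _fit_logit(data.iloc[train], y[train], predictors)
            lp = model.intercept + data.iloc[test][list(predictors)].to_numpy(float) @ model.coefficients
            p = expit(lp)
            aucs.append(float(roc_auc_score(y[test], p)))
            rocs.append(_roc_on_grid(y[test], p, grid))
            pooled_pred[pos : pos + len(test)] = p
            pooled_true[pos : pos + len(test)] = y[test]
            pos += len(test)
    pooled_pred = pooled_pred[:pos]
    pooled_true = pooled_true[:pos]
    pred_cls = (pooled_pred >= threshold).astype(int)
    tp = int(np.sum((pred_cls == 1) & (pooled_true == 1)))
    tn = int(np.sum((pred_cls == 0) & (pooled_true == 0)))
    fp = int(np.sum((pred_cls == 1) & (pooled_true == 0)))
    fn = int(np.sum((pred_cls == 0) & (pooled_true == 1)))
    sens = tp / (tp + fn) if tp + fn else np.nan
    spec = tn / (tn + fp) if tn + fp else np.nan
    roc_arr = np.vstack(rocs)
    return CVReport(
        predictors=list(predictors),
        repeats=repeats,
        folds=folds,
        seed=seed,
        aucs=np.asarray(aucs),
        accuracy=(tp + tn) / pos,
        sensitivity=sens,
        specificity=spec,
        balanced_accuracy=(sens + spec) / 2.0,
        roc_grid=grid,
        roc_mean=roc_arr.mean(axis=0),
        roc_band=(
            np.percentile(roc_arr, 2.5, axis=0),
            np.percentile(roc_arr, 97.5, axis=0),
        ),
        seed_schedule=schedule,
    )


def _roc_on_grid(y_true: np.ndarray, scores: np.ndarray, grid: np.ndarray) -> np.ndarray:
    from sklearn.metrics import roc_curve

    fpr, tpr, _ = roc_curve(y_true, scores)
    return np.interp(grid, fpr, tpr)


# ---------------------------------------------------------------------------
# Model object (statsmodels-style surface)
# ---------------------------------------------------------------------------

def prepare_classification_table(
    table: pd.DataFrame, status_col: str = "status", positive: str = "active"
) -> tuple[pd.DataFrame, np.ndarray]:
    """Drop controls and binarize status (active = 1, NED = 0)."""
    mel = table[table[status_col].isin(["NED", positive])].copy()
    y = (mel[status_col] == positive).to_numpy(int)
    return mel, y


class NedActiveLogit:
    """Logistic model of active vs NED status over chosen predictors.

    ``fit()`` returns the :class:`LogisticModel`; ``cross_validate()`` runs
    the repeated stratified CV protocol on the same specification.
    """

    def __init__(
        self,
        table: pd.DataFrame,
        predictors: Sequence[str],
        status_col: str = "status",
        positive: str = "active",
    ) -> None:
        self.data, self.y = prepare_classification_table(table, status_col, positive)
        missing = [p for p in predictors if p not in self.data.columns]
        if missing:
            raise KeyError(f"predictors not in table: {missing}")
        self.predictors = list(predictors)

    def fit(self) -> LogisticModel:
        return _fit_logit(self.data, self.y, self.predictors)

    def cross_validate(self, repeats: int = 25, folds: int = 5, seed: int = 0) -> CVReport:
        return cross_validate(
            self.data, self.predictors, self.y, repeats=repeats, folds=folds, seed=seed
        )
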