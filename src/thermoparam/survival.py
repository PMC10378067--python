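"""Overall- and progression-free-survival modelling of melanoma cohorts.

Active-disease overall survival (OS) is screened one thermogram parameter
at a time with Cox proportional-hazards regression (Efron tie handling,
Wald intervals), the unadjusted p-values are Benjamini–Hochberg corrected
across the 23-parameter family, and a multivariable model is reduced by
backward stepwise elimination under BIC (−2·log partial likelihood +
k·ln(events)).  The strongest parameter is visualized by Kaplan–Meier
curves dichotomized at its median (values at the median go to the lower
arm) with the Mantel–Cox log-rank test, and the arms are compared by
restricted mean survival time (RMST) up to a truncation time τ (default
8 years) with Greenwood plug-in variances.  The same univariate machinery
serves the NED group's progression-free survival.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import logrank_test
from scipy import stats

from .status import fdr_adjust

__all__ = [
    "CoxResult",
    "KMSplitResult",
    "RMSTResult",
    "cox_univariate",
    "cox_screen",
    "cox_backward_bic",
    "km_median_split",
    "rmst_greenwood",
    "rmst_compare",
    "pfs_analysis",
]


@dataclass
class CoxResult:
    """One Cox regression row (per parameter)."""

    parameter: str
    coefficient: float
    se: float
    hazard_ratio: float
    ci: tuple[float, float]            # 95% CI on the hazard-ratio scale
    p: float
    n: int
    n_events: int
    p_adjusted: float | None = None
    note: str = ""

    def format_hazard_ratio(self, digits: int = 2) -> str:
        lo, hi = self.ci
        return f"{self.hazard_ratio:.{digits}f} ({lo:.{digits}f}–{hi:.{digits}f})"

    def as_row(self) -> dict:
        return {
            "parameter": self.parameter,
            "coefficient": self.coefficient,
            "se": self.se,
            "hazard_ratio": self.hazard_ratio,
            "hr_ci_low": self.ci[0],
            "hr_ci_high": self.ci[1],
            "p": self.p,
            "p_adjusted": self.p_adjusted,
            "n": self.n,
            "n_events": self.n_events,
            "note": self.note,
        }


def _check_surv(time: np.ndarray, event: np.ndarray) -> None:
    if np.any(time <= 0):
        raise ValueError("survival times must be positive")
    if event.sum() < 1:
        raise ValueError("at least one event is required")


def _fit_cox(df: pd.DataFrame, covariates: Sequence[str]) -> CoxPHFitter:
    cph = CoxPHFitter()
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        cph.fit(
            df[["_time", "_event", *covariates]],
            duration_col="_time",
            event_col="_event",
        )
    cph._convergence_notes = "; ".join(
        str(w.message) for w in caught if "convergence" in str(w.message).lower()
    )
    return cph


def cox_univariate(
    values: Sequence[float],
    time: Sequence[float],
    event: Sequence[bool],
    name: str = "parameter",
) -> CoxResult:
    """Single-covariate Cox fit (Efron ties) with Wald CI and p-value."""
    x = np.asarray(values, dtype=float)
    t = np.asarray(time, dtype=float)
    e = np.asarray(event, dtype=bool)
    _check_surv(t, e)
    df = pd.DataFrame({"_time": t, "_event": e.astype(int), name: x})
    cph = _fit_cox(df, [name])
    row = cph.summary.loc[name]
    return CoxResult(
        parameter=name,
        coefficient=float(row["coef"]),
        se=float(row["se(coef)"]),
        hazard_ratio=float(row["exp(coef)"]),
        ci=(float(row["exp(coef) lower 95%"]), float(row["exp(coef) upper 95%"])),
        p=float(row["p"]),
        n=len(t),
        n_events=int(e.sum()),
        note=cph._convergence_notes,
    )


def cox_screen(
    table: pd.DataFrame,
    parameters: Sequence[str],
    time_col: str = "os_time",
    event_col: str = "os_event",
) -> tuple[pd.DataFrame, list[CoxResult]]:
    """Univariate Cox per parameter with family-wise BH adjustment."""
    results = [
        cox_univariate(table[p], table[time_col], table[event_col], name=p)
        for p in parameters
    ]
    adj = fdr_adjust([r.p for r in results])
    for r, a in zip(results, adj):
        r.p_adjusted = float(a)
    return pd.DataFrame([r.as_row() for r in results]), results


def _partial_ll(cph: CoxPHFitter) -> tuple[float, float]:
    """(fitted, null) partial log-likelihood of a lifelines Cox fit."""
    ll = float(cph.log_likelihood_)
    ll0 = ll - float(cph.log_likelihood_ratio_test().test_statistic) / 2.0
    return ll, ll0


def cox_backward_bic(
    table: pd.DataFrame,
    candidates: Sequence[str],
    time_col: str = "os_time",
    event_col: str = "os_event",
) -> list[CoxResult]:
    """Backward stepwise Cox elimination under BIC.

    BIC = −2·log partial likelihood + k·ln(number of events).  At each step
    the covariate whose removal most decreases BIC is dropped; elimination
    stops when no removal decreases BIC.  May return an empty model.
    """
    t = np.asarray(table[time_col], dtype=float)
    e = np.asarray(table[event_col], dtype=bool)
    _check_surv(t, e)
    d = float(e.sum())
    df = table[list(candidates)].astype(float).copy()
    df["_time"] = t
    df["_event"] = e.astype(int)

    def bic_of(subset: list[str]) -> float:
        if not subset:
            return -2.0 * _null_ll
        cph = _fit_cox(df, subset)
        ll, _ = _partial_ll(cph)
        return -2.0 * ll + len(subset) * np.log(d)

    full = _fit_cox(df, list(candidates))
    _, _null_ll = _partial_ll(full)
    current = list(candidates)
    current_bic = -2.0 * _partial_ll(full)[0] + len(current) * np.log(d)
    while current:
        options = [[c for c in current if c != drop] for drop in current]
        bics = [bic_of(o) for o in options]
        best = int(np.argmin(bics))
        if bics[best] < current_bic - 1e-10:
            current, current_bic = options[best], bics[best]
        else:
            break
    if not current:
        return []
    cph = _fit_cox(df, current)
    out = []
    for name in current:
        row = cph.summary.loc[name]
        out.append(
            CoxResult(
                parameter=name,
                coefficient=float(row["coef"]),
                se=float(row["se(coef)"]),
                hazard_ratio=float(row["exp(coef)"]),
                ci=(float(row["exp(coef) lower 95%"]), float(row["exp(coef) upper 95%"])),
                p=float(row["p"]),
                n=len(t),
                n_events=int(e.sum()),
                note=cph._convergence_notes,
            )
        )
    return out


# ---------------------------------------------------------------------------
# Kaplan–Meier median split and RMST
# ---------------------------------------------------------------------------

@dataclass
class KMSplitResult:
    """Median-dichotomized survival comparison."""

    median_value: float
    fitters: dict[str, KaplanMeierFitter]     # 'above' / 'at-or-below'
    logrank_statistic: float
    logrank_p: float
    n: dict[str, int]

    def survival_table(self) -> pd.DataFrame:
        frames = []
        for label, kmf in self.fitters.items():
            sf = kmf.survival_function_.copy()
            sf.columns = [label]
            frames.append(sf)
        return pd.concat(frames, axis=1)


def km_median_split(
    values: Sequence[float],
    time: Sequence[float],
    event: Sequence[bool],
) -> KMSplitResult:
    """Product-limit curves above vs at-or-below the parameter median, with
    the Mantel–Cox (log-rank) test."""
    x = np.asarray(values, dtype=float)
    t = np.asarray(time, dtype=float)
    e = np.asarray(event, dtype=bool)
    _check_surv(t, e)
    med = float(np.median(x))
    above = x > med
    if above.sum() < 2 or (~above).sum() < 2:
        raise ValueError("cannot split: fewer than two samples on one side of the median")
    fitters = {}
    for label, mask in (("above", above), ("at-or-below", ~above)):
        kmf = KaplanMeierFitter(label=label)
        kmf.fit(t[mask], e[mask])
        fitters[label] = kmf
    lr = logrank_test(t[above], t[~above], event_observed_A=e[above], event_observed_B=e[~above])
    return KMSplitResult(
        median_value=med,
        fitters=fitters,
        logrank_statistic=float(lr.test_statistic),
        logrank_p=float(lr.p_value),
        n={"above": int(above.sum()), "at-or-below": int((~above).sum())},
    )


def rmst_greenwood(
    time: Sequence[float], event: Sequence[bool], tau: float
) -> tuple[float, float]:
    """RMST (area under the Kaplan–Meier step function up to τ) and its
    Greenwood plug-in variance.

    Variance = Σ_i a_i² · d_i / (n_i (n_i − d_i)) over event times t_i <= τ,
    where a_i = ∫_{t_i}^{τ} Ŝ(u) du; terms with n_i = d_i contribute 0.
    """
    t = np.asarray(time, dtype=float)
    e = np.asarray(event, dtype=bool)
    _check_surv(t, e)
    if tau <= 0:
        raise ValueError("tau must be positive")
    uniq = np.unique(t)
    n_at_risk = t.size
    surv = 1.0
    prev = 0.0
    rmst = 0.0
    # per event time <= tau: (d, n, S after the event, segment start)
    ev_d: list[float] = []
    ev_n: list[float] = []
    seg_start: list[float] = []
    seg_surv: list[float] = []
    for ti in uniq:
        d = int(np.sum((t == ti) & e))
        c = int(np.sum((t == ti) & ~e))
        if ti > tau:
            break
        rmst += surv * (ti - prev)
        prev = ti
        if d > 0:
            surv *= 1.0 - d / n_at_risk
            ev_d.append(d)
            ev_n.append(n_at_risk)
            seg_start.append(ti)
            seg_surv.append(surv)
        n_at_risk -= d + c
    rmst += surv * (tau - prev)
    # a_i: tail integrals of the step function from each event time to tau
    var = 0.0
    if ev_d:
        bounds = seg_start[1:] + [tau]
        seg_area = [
            s * max(b - a, 0.0) for s, a, b in zip(seg_surv, seg_start, bounds)
        ]
        tail = np.concatenate([np.cumsum(seg_area[::-1])[::-1]])
        for a_i, d, n in zip(tail, ev_d, ev_n):
            if n > d:
                var += a_i**2 * d / (n * (n - d))
    return float(rmst), float(var)


@dataclass
class RMSTResult:
    """Restricted-mean-survival comparison of two groups at truncation τ."""

    tau: float
    rmst: dict[str, float]
    ci: dict[str, tuple[float, float]]
    difference: float                        # first label − second label
    difference_ci: tuple[float, float]
    p: float
    labels: tuple[str, str]

    def as_row(self) -> dict:
        (a, b) = self.labels
        return {
            "tau": self.tau,
            f"rmst_{a}": self.rmst[a],
            f"rmst_{b}": self.rmst[b],
            "difference": self.difference,
            "diff_ci_low": self.difference_ci[0],
            "diff_ci_high": self.difference_ci[1],
            "p": self.p,
        }


def rmst_compare(
    group: Sequence,
    time: Sequence[float],
    event: Sequence[bool],
    tau: float = 8.0,
    level_order: tuple | None = None,
    ci_level: float = 0.95,
) -> RMSTResult:
    """Restricted mean survival time per group up to τ, with Greenwood
    plug-in variances and a normal-theory test of the difference.

    The difference is ``level_order[0] − level_order[1]``.  If τ exceeds the
    last observed time in a group, it is clipped to that time with a
    warning.
    """
    g = np.asarray(group)
    t = np.asarray(time, dtype=float)
    e = np.asarray(event, dtype=bool)
    _check_surv(t, e)
    levels = list(level_order) if level_order is not None else sorted(set(g.tolist()))
    if len(levels) != 2:
        raise ValueError("rmst_compare needs exactly two group levels")
    rmst: dict[str, float] = {}
    var: dict[str, float] = {}
    ci: dict[str, tuple[float, float]] = {}
    zq = stats.norm.ppf(0.5 + ci_level / 2.0)
    for lev in levels:
        mask = g == lev
        if mask.sum() < 2:
            raise ValueError(f"group {lev!r} has fewer than two samples")
        t_g, e_g = t[mask], e[mask]
        tau_g = tau
        if tau_g > t_g.max():
            warnings.warn(
                f"tau={tau} beyond last observed time in group {lev!r}; "
                f"clipped to {t_g.max():.3g}",
                stacklevel=2,
            )
            tau_g = float(t_g.max())
        mu, v = rmst_greenwood(t_g, e_g, tau_g)
        rmst[str(lev)] = mu
        var[str(lev)] = v
        half = zq * np.sqrt(max(v, 0.0))
        ci[str(lev)] = (mu - half, mu + half)
    a, b = (str(levels[0]), str(levels[1]))
    diff = rmst[a] - rmst[b]
    sd = np.sqrt(var[a] + var[b])
    p = float(2.0 * stats.norm.sf(abs(diff) / sd)) if sd > 0 else 1.0
    return RMSTResult(
        tau=tau,
        rmst=rmst,
        ci=ci,
        difference=diff,
        difference_ci=(diff - zq * sd, diff + zq * sd),
        p=p,
        labels=(a, b),
    )


def pfs_analysis(
    table: pd.DataFrame,
    parameters: Sequence[str],
    time_col: str = "pfs_time",
    event_col: str = "pfs_event",
    status_col: str = "status",
) -> tuple[pd.DataFrame, list[CoxResult]]:
    """Univariate Cox screen of NED progression-free survival.

    Restricts to NED records with PFS follow-up; low-event fits are
    expected and produce wide intervals rather than errors (zero events
    still raise).
    """
    ned = table[table[status_col] == "NED"] if status_col in table.columns else table
    ned = ned.dropna(subset=[time_col, event_col])
    if len(ned) == 0:
        raise ValueError("no NED records with PFS data")
    return cox_screen(ned, parameters, time_col=time_col, event_col=event_col)
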