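"""ROC-based MTV cut-off selection and low- vs high-MTV survival analysis.

MTV is dichotomised at the cut-off minimising
``(1 − sensitivity)² + (1 − specificity)²`` over the ROC curve (the point
nearest the top-left corner), where the ROC outcome is a binary progression
indicator within a fixed horizon (5 years by default).  Patients censored
before the horizon are excluded from the ROC sweep but retained in
Kaplan–Meier, log-rank and Cox analyses, which use full right-censored
times.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "DAYS_PER_YEAR",
    "HORIZON_5Y_DAYS",
    "RocResult",
    "GroupSurvival",
    "validate_cohort",
    "binary_outcome",
    "roc_curve",
    "optimal_cutoff",
    "dichotomize",
    "km_estimate",
    "logrank_test",
    "cox_univariate",
    "survival_report",
]

DAYS_PER_YEAR: float = 365.25
HORIZON_5Y_DAYS: float = 5 * DAYS_PER_YEAR

#: Columns a cohort table must provide (plus one MTV column per method).
COHORT_COLUMNS = ("patient_id", "time_pfs", "event_pfs", "time_os", "event_os")


@dataclass(frozen=True)
class RocResult:
    """ROC sweep over all unique MTV values as candidate cut-offs."""

    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float
    auc_ci: Tuple[float, float]

    def __post_init__(self):
        if not 0 <= self.auc <= 1:
            raise ValueError("AUC must lie in [0, 1]")


@dataclass(frozen=True)
class GroupSurvival:
    """Kaplan–Meier summary for one MTV group.

    ``median_survival`` is NaN when the curve never reaches 50% (no median
    available); ``km_curve`` holds the step function as (times, survival).
    """

    group: str
    n: int
    events: int
    surv_5y: float
    median_survival: float
    km_curve: Tuple[np.ndarray, np.ndarray]

    def __post_init__(self):
        if not 0 <= self.surv_5y <= 1:
            raise ValueError("surv_5y must lie in [0, 1]")
        if self.events > self.n:
            raise ValueError("events cannot exceed n")


def validate_cohort(df: pd.DataFrame, mtv_columns: Sequence[str]) -> None:
    """Schema check before any computation; raises on violation."""
    missing = set(COHORT_COLUMNS).union(mtv_columns) - set(df.columns)
    if missing:
        raise ValueError(f"cohort table missing columns: {sorted(missing)}")
    for tcol in ("time_pfs", "time_os"):
        if (df[tcol] <= 0).any():
            raise ValueError(f"{tcol} must be > 0")
    for ecol in ("event_pfs", "event_os"):
        if not df[ecol].isin([0, 1]).all():
            raise ValueError(f"{ecol} must be binary")
    for mcol in mtv_columns:
        if (df[mcol] < 0).any():
            raise ValueError(f"{mcol} must be >= 0")


def binary_outcome(
    times: Sequence[float], events: Sequence[int], horizon_days: float = HORIZON_5Y_DAYS
) -> Tuple[np.ndarray, np.ndarray]:
    """Binary endpoint for ROC: progressed/died within the horizon.

    Returns ``(outcome, include)``: outcome 1 for an event at or before the
    horizon, 0 for follow-up beyond the horizon, and ``include`` False for
    patients censored before the horizon (indeterminate endpoint).
    """
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    outcome = ((e == 1) & (t <= horizon_days)).astype(int)
    include = (t > horizon_days) | (e == 1)
    return outcome, include


def _delong_auc_ci(scores: np.ndarray, labels: np.ndarray, level: float) -> Tuple[float, float, float]:
    """AUC with DeLong variance via midrank placement values."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    m, n = pos.size, neg.size
    r_all = sps.rankdata(np.concatenate([pos, neg]))
    r_pos = sps.rankdata(pos)
    r_neg = sps.rankdata(neg)
    auc = (r_all[:m].sum() - m * (m + 1) / 2.0) / (m * n)
    v10 = (r_all[:m] - r_pos) / n          # placements of positives among negatives
    v01 = 1.0 - (r_all[m:] - r_neg) / m    # placements of negatives among positives
    var = (np.var(v10, ddof=1) / m if m > 1 else 0.0) + (
        np.var(v01, ddof=1) / n if n > 1 else 0.0
    )
    z = sps.norm.ppf(0.5 + level / 2.0)
    half = z * np.sqrt(var)
    return float(auc), float(max(auc - half, 0.0)), float(min(auc + half, 1.0))


def roc_curve(
    mtv: Sequence[float],
    outcome: Sequence[int],
    ci_method: str = "delong",
    ci_level: float = 0.95,
    n_boot: int = 2000,
    rng: Optional[np.random.Generator] = None,
) -> RocResult:
    """ROC over candidate cut-offs = the unique MTV values (ascending).

    A patient is classified high-risk when ``mtv >= t`` (inclusive).  AUC is
    the trapezoidal area; its confidence interval comes from the DeLong
    variance (default) or a stratified bootstrap (``ci_method="bootstrap"``).
    """
    x = np.asarray(mtv, dtype=float)
    y = np.asarray(outcome, dtype=int)
    if x.size != y.size:
        raise ValueError("mtv and outcome lengths differ")
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("degenerate ROC: both outcome classes must be present")
    thresholds = np.unique(x)
    # counts of positives/negatives at or above each threshold, vectorised
    pred = x[None, :] >= thresholds[:, None]
    tp = (pred & (y == 1)).sum(axis=1)
    fp = (pred & (y == 0)).sum(axis=1)
    sens = tp / n_pos
    spec = 1.0 - fp / n_neg
    if ci_method == "delong":
        auc, lo, hi = _delong_auc_ci(x, y, ci_level)
    elif ci_method == "bootstrap":
        from sklearn.metrics import roc_auc_score

        auc = float(roc_auc_score(y, x))
        rng = rng or np.random.default_rng(0)
        boots = []
        idx_pos = np.flatnonzero(y == 1)
        idx_neg = np.flatnonzero(y == 0)
        for _ in range(n_boot):
            bi = np.concatenate(
                [rng.choice(idx_pos, n_pos), rng.choice(idx_neg, n_neg)]
            )
            boots.append(roc_auc_score(y[bi], x[bi]))
        a = (1 - ci_level) / 2 * 100
        lo, hi = np.percentile(boots, [a, 100 - a])
    else:
        raise ValueError(f"unknown ci_method {ci_method!r}")
    return RocResult(thresholds, sens, spec, auc, (float(lo), float(hi)))


def optimal_cutoff(roc: RocResult) -> Tuple[float, float, float]:
    """Cut-off nearest the top-left corner of the ROC curve.

    Minimises ``(1 − sens)² + (1 − spec)²``; among ties the smallest
    threshold is returned (favours sensitivity).
    """
    d2 = (1.0 - roc.sensitivity) ** 2 + (1.0 - roc.specificity) ** 2
    i = int(np.flatnonzero(d2 == d2.min())[0])  # thresholds ascending
    return float(roc.thresholds[i]), float(roc.sensitivity[i]), float(roc.specificity[i])


def dichotomize(mtv: Sequence[float], cutoff: float) -> np.ndarray:
    """'high' iff mtv >= cutoff (inclusive), else 'low'."""
    if cutoff <= 0:
        raise ValueError("cutoff must be > 0")
    return np.where(np.asarray(mtv, dtype=float) >= cutoff, "high", "low")


def km_estimate(
    times: Sequence[float], events: Sequence[int], group: str = "all"
) -> GroupSurvival:
    """Product-limit survival curve with 5-year read-off and median."""
    from lifelines import KaplanMeierFitter

    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    if t.size < 1:
        raise ValueError("need at least one subject")
    if np.any(t < 0):
        raise ValueError("survival times must be non-negative")
    kmf = KaplanMeierFitter()
    kmf.fit(t, e)
    surv = kmf.survival_function_["KM_estimate"]
    s5 = float(kmf.predict(HORIZON_5Y_DAYS))
    med = kmf.median_survival_time_
    med = float("nan") if np.isinf(med) else float(med)
    return GroupSurvival(
        group=group,
        n=int(t.size),
        events=int(e.sum()),
        surv_5y=s5,
        median_survival=med,
        km_curve=(surv.index.to_numpy(dtype=float), surv.to_numpy(dtype=float)),
    )


def logrank_test(
    times_a: Sequence[float],
    events_a: Sequence[int],
    times_b: Sequence[float],
    events_b: Sequence[int],
) -> Tuple[float, float]:
    """One-degree-of-freedom log-rank chi² and p for two survival curves."""
    from lifelines.statistics import logrank_test as _lr

    if len(times_a) == 0 or len(times_b) == 0:
        raise ValueError("both groups must be non-empty")
    res = _lr(times_a, times_b, event_observed_A=events_a, event_observed_B=events_b)
    return float(res.test_statistic), float(res.p_value)


def _breslow_loglik(beta: float, t: np.ndarray, e: np.ndarray, x: np.ndarray):
    """Breslow partial log-likelihood, score and information for one binary
    covariate.  Tied event times share one risk set (Breslow convention)."""
    order = np.argsort(t, kind="stable")
    t, e, x = t[order], e[order], x[order]
    # suffix sums over risk sets R(t_i) = {j : t_j >= t_i}; tied event times
    # share one risk set, so index each subject at the first of its ties
    ex = np.exp(beta * x)
    s0 = np.cumsum(ex[::-1])[::-1]          # sum exp(beta x) over risk set
    s1 = np.cumsum((x * ex)[::-1])[::-1]    # sum x exp(beta x)
    first = np.searchsorted(t, t, side="left")
    s0, s1 = s0[first], s1[first]
    # with x binary, x**2 == x so s2 == s1
    ev = e == 1
    ll = float(np.sum(beta * x[ev] - np.log(s0[ev])))
    xbar = s1[ev] / s0[ev]
    score = float(np.sum(x[ev] - xbar))
    info = float(np.sum(xbar * (1.0 - xbar)))
    return ll, score, info


def cox_univariate(
    times: Sequence[float],
    events: Sequence[int],
    group: Sequence[str],
    ties: str = "breslow",
) -> Tuple[float, float, float, float]:
    """Univariate Cox HR for high vs low MTV with Wald 95% CI and p.

    ``ties`` selects the Breslow (default; Newton–Raphson on the 1-D partial
    likelihood) or Efron (via lifelines) approximation.  Monotone likelihood
    — complete separation of events between the groups — raises a
    non-convergence error with a diagnostic.
    """
    g = np.asarray(group)
    x = (g == "high").astype(float)
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    if len(set(g.tolist())) < 2:
        raise ValueError("both MTV groups must be present")
    if e[x == 1].sum() < 1 or e[x == 0].sum() < 1:
        raise ValueError("each group needs at least one event for a stable HR")
    if ties == "efron":
        from lifelines import CoxPHFitter
        from lifelines.exceptions import ConvergenceError

        df = pd.DataFrame({"T": t, "E": e, "high": x})
        cph = CoxPHFitter()
        try:
            cph.fit(df, duration_col="T", event_col="E")
        except ConvergenceError as exc:
            raise RuntimeError(f"Cox model failed to converge: {exc}") from exc
        row = cph.summary.loc["high"]
        beta, se = float(row["coef"]), float(row["se(coef)"])
    elif ties == "breslow":
        beta = 0.0
        for it in range(50):
            _, score, info = _breslow_loglik(beta, t, e, x)
            if info <= 1e-12:
                raise RuntimeError(
                    "Cox model failed to converge: zero information "
                    "(complete separation of events between groups)"
                )
            step = score / info
            beta += np.clip(step, -5.0, 5.0)
            if abs(step) < 1e-10:
                break
        else:
            raise RuntimeError(
                f"Cox model failed to converge after 50 iterations (beta={beta:.3g}); "
                "likelihood may be monotone"
            )
        if abs(beta) > 30:
            raise RuntimeError(
                f"Cox model diverged (|beta|={abs(beta):.3g}); monotone likelihood"
            )
        _, _, info = _breslow_loglik(beta, t, e, x)
        se = 1.0 / np.sqrt(info)
    else:
        raise ValueError(f"unknown ties method {ties!r}")
    z = sps.norm.ppf(0.975)
    p = float(2 * sps.norm.sf(abs(beta) / se))
    return (
        float(np.exp(beta)),
        float(np.exp(beta - z * se)),
        float(np.exp(beta + z * se)),
        p,
    )


def survival_report(
    df: pd.DataFrame,
    mtv_column: str,
    endpoint: str = "pfs",
    horizon_days: float = HORIZON_5Y_DAYS,
    ci_method: str = "delong",
    cutoff: Optional[float] = None,
) -> dict:
    """Per-method prognostic block: ROC, cut-off, KM by group, log-rank, Cox.

    ``cutoff=None`` derives the cut-off from the ROC on this endpoint;
    passing a value reuses a cut-off derived elsewhere (e.g. the PFS-derived
    cut-off applied to OS).
    """
    tcol, ecol = f"time_{endpoint}", f"event_{endpoint}"
    validate_cohort(df, [mtv_column])
    mtv = df[mtv_column].to_numpy(dtype=float)
    t = df[tcol].to_numpy(dtype=float)
    e = df[ecol].to_numpy(dtype=int)
    outcome, include = binary_outcome(t, e, horizon_days)
    roc = roc_curve(mtv[include], outcome[include], ci_method=ci_method)
    thr, sens, spec = optimal_cutoff(roc)
    if cutoff is None:
        cutoff = thr
    groups = dichotomize(mtv, cutoff)
    low, high = groups == "low", groups == "high"
    km_low = km_estimate(t[low], e[low], "low")
    km_high = km_estimate(t[high], e[high], "high")
    chi2, p_lr = logrank_test(t[low], e[low], t[high], e[high])
    hr, ci_lo, ci_hi, p_cox = cox_univariate(t, e, groups)
    return {
        "method": mtv_column,
        "endpoint": endpoint,
        "auc": roc.auc,
        "auc_ci": list(roc.auc_ci),
        "optimal_threshold_cm3": thr,
        "optimal_sensitivity": sens,
        "optimal_specificity": spec,
        "cutoff_used_cm3": float(cutoff),
        "n_roc": int(include.sum()),
        "groups": {
            "low": {
                "n": km_low.n,
                "events": km_low.events,
                "surv_5y": km_low.surv_5y,
                "median_survival_days": km_low.median_survival,
            },
            "high": {
                "n": km_high.n,
                "events": km_high.events,
                "surv_5y": km_high.surv_5y,
                "median_survival_days": km_high.median_survival,
            },
        },
        "logrank_chi2": chi2,
        "logrank_p": p_lr,
        "cox_hr": hr,
        "cox_hr_ci": [ci_lo, ci_hi],
        "cox_p": p_cox,
    }
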