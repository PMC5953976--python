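"""Method- and observer-agreement statistics for paired MTV measurements.

MTV distributions are strongly right-skewed, so the workflow is:
Kolmogorov–Smirnov normality pre-check, cube-root transform to restore
approximate normality before the intraclass correlation coefficient (ICC),
Kendall's tau-b on ranks, and a *non-parametric* Bland–Altman analysis of
the untransformed values (median bias; limits of agreement as the 2.5th and
97.5th percentiles of the paired differences).
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Sequence, Tuple

import numpy as np
from scipy import stats as sps

__all__ = [
    "PairedMeasurements",
    "AgreementReport",
    "ks_normality",
    "cube_root_transform",
    "icc_consistency",
    "kendall_tau",
    "bland_altman",
    "agreement_report",
]


@dataclass(frozen=True)
class PairedMeasurements:
    """Congruent MTV lists from two methods or observers (A and B)."""

    ids: Tuple[str, ...]
    a: np.ndarray
    b: np.ndarray

    def __post_init__(self):
        a = np.asarray(self.a, dtype=float)
        b = np.asarray(self.b, dtype=float)
        ids = tuple(str(i) for i in self.ids)
        if not (len(ids) == a.size == b.size):
            raise ValueError("ids, a and b must have equal lengths")
        if a.size < 3:
            raise ValueError("need at least 3 paired measurements")
        if np.any(~np.isfinite(a)) or np.any(~np.isfinite(b)):
            raise ValueError("missing/non-finite entries are not allowed")
        if np.any(a < 0) or np.any(b < 0):
            raise ValueError("MTV values must be >= 0")
        object.__setattr__(self, "ids", ids)
        object.__setattr__(self, "a", a)
        object.__setattr__(self, "b", b)

    @property
    def n(self) -> int:
        return self.a.size


@dataclass(frozen=True)
class AgreementReport:
    """One row of the pairwise agreement table.

    Differences are oriented A − B in the order the caller supplied the
    lists; ``orientation`` records that convention.
    """

    pair: str
    icc: float
    icc_p: float
    tau: float
    tau_p: float
    median_diff: float
    loa_low: float
    loa_high: float
    trend_slope: float
    orientation: str = "A-B"

    def __post_init__(self):
        if not (self.loa_low <= self.median_diff <= self.loa_high):
            raise ValueError("limits of agreement must bracket the median difference")

    def as_dict(self) -> dict:
        return asdict(self)


def ks_normality(values: Sequence[float], lilliefors: bool = True) -> float:
    """One-sample KS normality p-value with estimated mean/SD.

    By default the Lilliefors correction accounts for estimating the normal
    parameters from the sample (the uncorrected KS test against
    N(mean, SD) is anticonservative).  Requires n >= 5.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 5:
        raise ValueError(f"normality test needs n >= 5, got {x.size}")
    if lilliefors:
        from statsmodels.stats.diagnostic import lilliefors as _lf

        return float(_lf(x, dist="norm", pvalmethod="table")[1])
    return float(sps.kstest(x, "norm", args=(x.mean(), x.std(ddof=1))).pvalue)


def cube_root_transform(values: Sequence[float]) -> np.ndarray:
    """Elementwise cube root; order-preserving; domain v >= 0."""
    x = np.asarray(values, dtype=float)
    if np.any(x < 0):
        raise ValueError("cube-root transform requires non-negative values")
    return np.cbrt(x)


def icc_consistency(
    pairs: PairedMeasurements, transform: str = "cube_root"
) -> Tuple[float, float]:
    """Two-way mixed-effects, single-rater, consistency ICC (ICC(3,1)).

    The ANOVA decomposition over the n × 2 table gives
    ``ICC = (MSR − MSE) / (MSR + (k−1) MSE)`` with MSR the between-subject
    and MSE the residual mean square; the p-value is from the F test
    ``MSR/MSE`` on (n−1, (n−1)(k−1)) degrees of freedom.  ``transform``
    applies the cube root first (the default, matching the skewed-MTV
    workflow) or nothing (``"none"``).
    """
    if transform == "cube_root":
        x = np.column_stack([cube_root_transform(pairs.a), cube_root_transform(pairs.b)])
    elif transform == "none":
        x = np.column_stack([pairs.a, pairs.b])
    else:
        raise ValueError(f"unknown transform {transform!r}")
    n, k = x.shape
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ss_rows = k * float(((row_means - grand) ** 2).sum())
    ss_cols = n * float(((col_means - grand) ** 2).sum())
    ss_total = float(((x - grand) ** 2).sum())
    ss_err = max(ss_total - ss_rows - ss_cols, 0.0)
    msr = ss_rows / (n - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    if msr == 0.0 and mse == 0.0:
        raise ValueError("ICC undefined: zero variance in both lists")
    if mse == 0.0:
        return 1.0, 0.0
    icc = (msr - mse) / (msr + (k - 1) * mse)
    f = msr / mse
    p = float(sps.f.sf(f, n - 1, (n - 1) * (k - 1)))
    return float(icc), p


def kendall_tau(pairs: PairedMeasurements) -> Tuple[float, float]:
    """Kendall's tau-b (tie-corrected) with asymptotic p-value."""
    if np.all(pairs.a == pairs.a[0]) and np.all(pairs.b == pairs.b[0]):
        raise ValueError("tau undefined: all pairs tied")
    res = sps.kendalltau(pairs.a, pairs.b, variant="b", method="asymptotic")
    return float(res.statistic), float(res.pvalue)


def bland_altman(pairs: PairedMeasurements) -> Tuple[float, float, float, float]:
    """Non-parametric Bland–Altman summary of paired differences A − B.

    Returns ``(median_diff, loa_low, loa_high, trend_slope)``: the median
    difference, the 2.5th / 97.5th percentiles of the differences
    (linear-interpolation quantiles), and the least-squares slope of the
    difference on the pairwise mean.  The slope is reported to flag a trend
    of difference with magnitude; it is descriptive, not tested.
    """
    d = pairs.a - pairs.b
    m = (pairs.a + pairs.b) / 2.0
    lo, hi = np.percentile(d, [2.5, 97.5], method="linear")
    if np.ptp(m) == 0:
        slope = 0.0
    else:
        slope = float(sps.linregress(m, d).slope)
    return float(np.median(d)), float(lo), float(hi), slope


def agreement_report(
    pairs: PairedMeasurements,
    pair_name: str = "A vs. B",
    icc_transform: str = "cube_root",
) -> AgreementReport:
    """Full agreement row: ICC (on transformed values), tau, Bland–Altman."""
    icc, icc_p = icc_consistency(pairs, transform=icc_transform)
    tau, tau_p = kendall_tau(pairs)
    med, lo, hi, slope = bland_altman(pairs)
    return AgreementReport(
        pair=pair_name,
        icc=icc,
        icc_p=icc_p,
        tau=tau,
        tau_p=tau_p,
        median_diff=med,
        loa_low=lo,
        loa_high=hi,
        trend_slope=slope,
    )
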