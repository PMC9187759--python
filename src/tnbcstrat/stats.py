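"""Statistical layer: correlation tests, KS tests, survival curves.

Conventions mirror the analysis this package reproduces: correlation
significance comes from linear regression (the t transform of Pearson's
r, identical to the regression-slope test), distributional differences
use the two-sample Kolmogorov-Smirnov test, survival curves use the
Kaplan-Meier product-limit estimator (via lifelines), and alpha = 0.05
with no multiple-testing correction is the default significance policy
(Benjamini-Hochberg is available but off).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank
from scipy import stats as sps

from .datatypes import ScoreVector

__all__ = [
    "TestResult",
    "SurvivalCurve",
    "pearson_test",
    "ks_two_sample",
    "ks_statistic",
    "kaplan_meier",
    "logrank_test",
    "correlation_matrix",
]

DEFAULT_ALPHA = 0.05


@dataclass
class TestResult:
    statistic: float
    pvalue: float
    test_name: str
    sample_sizes: tuple[int, ...]
    alpha: float = DEFAULT_ALPHA
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0 <= self.pvalue <= 1:
            raise ValueError(f"p-value {self.pvalue} outside [0, 1]")

    @property
    def significant(self) -> bool:
        return self.pvalue < self.alpha


@dataclass
class SurvivalCurve:
    """Kaplan-Meier step function with per-event-time bookkeeping."""

    event_times: np.ndarray       # distinct times with >= 1 death
    at_risk: np.ndarray           # number at risk just before each event time
    deaths: np.ndarray            # deaths at each event time
    survival: np.ndarray          # S(t) just after each event time
    censor_times: np.ndarray      # censoring times, for tick marks
    n: int

    def survival_at(self, t: float) -> float:
        """S(t) for any t >= 0 (right-continuous step function)."""
        idx = np.searchsorted(self.event_times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time": self.event_times,
                "at_risk": self.at_risk,
                "deaths": self.deaths,
                "survival": self.survival,
            }
        )


def pearson_test(x: ScoreVector, y: ScoreVector, alpha: float = DEFAULT_ALPHA) -> TestResult:
    """Pearson r with the two-sided regression-slope p-value.

    p comes from t = r * sqrt((n-2) / (1-r^2)) on n-2 degrees of
    freedom, which is algebraically the t test of the regression slope.
    """
    shared = x.values.index.intersection(y.values.index)
    xs = x.values.loc[shared].to_numpy(dtype=float)
    ys = y.values.loc[shared].to_numpy(dtype=float)
    n = len(shared)
    if n < 3:
        raise ValueError(f"need >= 3 paired values, got {n}")
    if np.ptp(xs) == 0 or np.ptp(ys) == 0:
        raise ValueError("undefined correlation: constant vector")
    xs_c, ys_c = xs - xs.mean(), ys - ys.mean()
    r = float(np.dot(xs_c, ys_c) / math.sqrt(np.dot(xs_c, xs_c) * np.dot(ys_c, ys_c)))
    r = max(-1.0, min(1.0, r))
    if abs(r) == 1.0:
        p = 0.0
    else:
        t = r * math.sqrt((n - 2) / (1 - r * r))
        p = 2.0 * sps.t.sf(abs(t), df=n - 2)
    return TestResult(
        statistic=r,
        pvalue=float(p),
        test_name="pearson",
        sample_sizes=(n,),
        alpha=alpha,
        extra={"x": x.name, "y": y.name},
    )


def ks_statistic(x: np.ndarray, y: np.ndarray) -> float:
    """D = sup |ECDF_x - ECDF_y|, evaluated at the pooled sorted points."""
    x = np.sort(np.asarray(x, dtype=float))
    y = np.sort(np.asarray(y, dtype=float))
    pooled = np.concatenate([x, y])
    fx = np.searchsorted(x, pooled, side="right") / len(x)
    fy = np.searchsorted(y, pooled, side="right") / len(y)
    return float(np.max(np.abs(fx - fy)))


def ks_two_sample(
    x, y, mode: str = "asymptotic", alpha: float = DEFAULT_ALPHA
) -> TestResult:
    """Two-sample KS test; exact p by full labeling enumeration when small.

    ``exact_small`` enumerates all C(n+m, n) assignments of the pooled
    values to the two samples (permitted for n+m <= 12) and reports the
    fraction with D at least as large as observed.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be non-empty")
    d = ks_statistic(x, y)
    if mode == "exact_small":
        n, m = len(x), len(y)
        if n + m > 12:
            raise ValueError("exact_small only for n + m <= 12")
        pooled = np.concatenate([x, y])
        idx = range(n + m)
        total = 0
        hits = 0
        for comb in combinations(idx, n):
            mask = np.zeros(n + m, dtype=bool)
            mask[list(comb)] = True
            d_perm = ks_statistic(pooled[mask], pooled[~mask])
            total += 1
            if d_perm >= d - 1e-12:
                hits += 1
        p = hits / total
    elif mode == "asymptotic":
        p = float(sps.ks_2samp(x, y, method="asymp").pvalue)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return TestResult(
        statistic=d,
        pvalue=float(p),
        test_name=f"ks_{mode}",
        sample_sizes=(len(x), len(y)),
        alpha=alpha,
    )


def kaplan_meier(times, events) -> SurvivalCurve:
    """Product-limit survival estimate.

    Censored observations at an event time count as at risk for that
    event time (the standard convention).
    """
    times = np.asarray(times, dtype=float).ravel()
    events = np.asarray(events).astype(bool).ravel()
    if len(times) == 0:
        raise ValueError("empty survival input")
    if len(times) != len(events):
        raise ValueError("times and events must have equal length")
    if (times < 0).any():
        raise ValueError("negative survival times")
    kmf = KaplanMeierFitter()
    kmf.fit(times, event_observed=events)
    et = kmf.event_table
    death_rows = et[et["observed"] > 0]
    # skip lifelines' synthetic t=0 row unless real deaths occur there
    event_times = death_rows.index.to_numpy(dtype=float)
    at_risk = death_rows["at_risk"].to_numpy(dtype=float)
    deaths = death_rows["observed"].to_numpy(dtype=float)
    surv = np.array(
        [float(kmf.survival_function_at_times(t).iloc[0]) for t in event_times]
    )
    return SurvivalCurve(
        event_times=event_times,
        at_risk=at_risk,
        deaths=deaths,
        survival=surv,
        censor_times=np.sort(times[~events]),
        n=len(times),
    )


def logrank_test(
    times_a, events_a, times_b, events_b, alpha: float = DEFAULT_ALPHA
) -> TestResult:
    """Standard log-rank chi-square (1 df) comparing two survival curves."""
    times_a = np.asarray(times_a, dtype=float)
    times_b = np.asarray(times_b, dtype=float)
    events_a = np.asarray(events_a).astype(bool)
    events_b = np.asarray(events_b).astype(bool)
    if len(times_a) == 0 or len(times_b) == 0:
        raise ValueError("both groups must be non-empty")
    warn = None
    if events_a.sum() == 0 or events_b.sum() == 0:
        warn = "a group has zero events; log-rank statistic is weakly informative"
        warnings.warn(warn)
    res = _ll_logrank(times_a, times_b, event_observed_A=events_a, event_observed_B=events_b)
    return TestResult(
        statistic=float(res.test_statistic),
        pvalue=float(res.p_value),
        test_name="logrank",
        sample_sizes=(len(times_a), len(times_b)),
        alpha=alpha,
        extra={"warning": warn} if warn else {},
    )


def correlation_matrix(
    scores: list[ScoreVector],
    target: ScoreVector,
    alpha: float = DEFAULT_ALPHA,
    bh_correct: bool = False,
) -> pd.DataFrame:
    """One Pearson test per score against the target score.

    Rows that fail (constant vector, too few shared samples) are marked
    failed rather than aborting the table. An optional
    Benjamini-Hochberg column can be added; it is off by default.
    """
    rows = []
    for s in scores:
        row = {"score": s.name, "n": len(s.values.index.intersection(target.values.index))}
        try:
            res = pearson_test(s, target, alpha=alpha)
            row.update(r=res.statistic, pvalue=res.pvalue,
                       significant=res.significant, failed=False, error=None)
        except ValueError as exc:
            row.update(r=np.nan, pvalue=np.nan, significant=False,
                       failed=True, error=str(exc))
        rows.append(row)
    table = pd.DataFrame(
        rows, columns=["score", "n", "r", "pvalue", "significant", "failed", "error"]
    )
    if bh_correct and len(table):
        from statsmodels.stats.multitest import multipletests

        ok = ~table["pvalue"].isna()
        adj = np.full(len(table), np.nan)
        if ok.any():
            adj[ok.to_numpy()] = multipletests(
                table.loc[ok, "pvalue"], method="fdr_bh"
            )[1]
        table["pvalue_bh"] = adj
    return table.set_index("score")
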