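"""Lifespan statistics: Kaplan-Meier curves, median contrasts, the log-rank
test, and the Wang/Allison maximal-lifespan quantile test.

The maximal-lifespan test compares, between two groups, the proportion of
animals still alive at the pooled age at which only 10% of all animals
remain alive, using a two-sided Fisher exact test on the resulting 2x2
table.  Kaplan-Meier estimation and the log-rank test are delegated to
lifelines; the quantile-test construction is implemented here.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank
from scipy import stats

log = logging.getLogger(__name__)

__all__ = [
    "KMCurve", "LogRankResult", "MaxLifeResult", "PercentChange",
    "km_estimate", "median_survival", "percent_change", "logrank_test",
    "maxlife_quantile_test",
]


@dataclass(frozen=True)
class KMCurve:
    """Product-limit estimate evaluated at the distinct event times."""

    event_times: np.ndarray   # ascending, events only
    survival: np.ndarray      # S(t) at each event time
    at_risk: np.ndarray       # n at risk just before each event time
    n_events: np.ndarray      # deaths at each event time


@dataclass(frozen=True)
class LogRankResult:
    chi2: float
    df: int
    p: float


@dataclass(frozen=True)
class PercentChange:
    raw: float
    one_decimal: float
    rounded: int

    @property
    def label(self) -> str:
        return f"{self.rounded}%"


@dataclass(frozen=True)
class MaxLifeResult:
    threshold_age: float
    counts: dict           # group -> (n_alive_beyond, n_total)
    p: float
    group_q90: dict        # group -> its own quantile lifespan
    percent_change_q90: float
    quantile: float
    n_censored_excluded: int

    @property
    def table(self) -> list[list[int]]:
        return [[a, t - a] for a, t in self.counts.values()]


def _group_arrays(table: pd.DataFrame, group: str) -> tuple[np.ndarray, np.ndarray]:
    sub = table[table["group"] == group]
    if sub.empty:
        raise ValueError(f"group {group!r} not present in the table")
    return sub["time"].to_numpy(float), sub["event"].to_numpy(int)


def km_estimate(table: pd.DataFrame, group: str) -> KMCurve:
    """Kaplan-Meier product-limit estimator for one group, with
    right-censoring support; tied deaths are simultaneous events."""
    times, events = _group_arrays(table, group)
    kmf = KaplanMeierFitter()
    kmf.fit(times, event_observed=events)
    et = kmf.event_table
    rows = et[et["observed"] > 0]
    event_times = rows.index.to_numpy(float)
    survival = kmf.survival_function_at_times(event_times).to_numpy(float)
    return KMCurve(
        event_times=event_times,
        survival=survival,
        at_risk=rows["at_risk"].to_numpy(int),
        n_events=rows["observed"].to_numpy(int),
    )


def median_survival(curve: KMCurve) -> float | None:
    """Smallest event time with S(t) <= 0.5; None when S never reaches 0.5."""
    hit = curve.survival <= 0.5 + 1e-12
    if not hit.any():
        return None
    return float(curve.event_times[int(np.argmax(hit))])


def percent_change(treated: float, control: float) -> PercentChange:
    """100 * (treated - control) / control, with the half-away-from-zero
    integer rendering used for headline percentages."""
    if control <= 0:
        raise ValueError("control value must be positive")
    raw = 100.0 * (treated - control) / control
    rounded = int(math.copysign(math.floor(abs(raw) + 0.5), raw))
    return PercentChange(raw=raw, one_decimal=round(raw, 1), rounded=rounded)


def logrank_test(table: pd.DataFrame, group_a: str, group_b: str) -> LogRankResult:
    """Standard two-group log-rank test with right censoring (df = 1)."""
    ta, ea = _group_arrays(table, group_a)
    tb, eb = _group_arrays(table, group_b)
    for g, e in ((group_a, ea), (group_b, eb)):
        if e.sum() == 0:
            log.warning("group %r has zero events; log-rank statistic is degenerate", g)
    res = _ll_logrank(ta, tb, event_observed_A=ea, event_observed_B=eb)
    return LogRankResult(chi2=float(res.test_statistic), df=1, p=float(res.p_value))


def _upper_order_statistic(values: np.ndarray, q: float) -> float:
    """Empirical quantile as the order statistic at ceil(q*n), 1-indexed —
    determinate under ties, no interpolation."""
    v = np.sort(values)
    idx = max(1, math.ceil(q * len(v)))
    return float(v[idx - 1])


def maxlife_quantile_test(table: pd.DataFrame, group_a: str, group_b: str,
                          quantile: float = 0.90) -> MaxLifeResult:
    """Maximal-lifespan comparison at the pooled upper quantile.

    The threshold is the pooled empirical ``quantile`` of observed lifespans
    (deaths only; censored animals are excluded with a logged count).  Each
    group contributes a (lifespan strictly beyond threshold) vs not count to
    a 2x2 table tested with a two-sided Fisher exact test.  Also reports each
    group's own quantile lifespan and its percent change (a vs b as control).
    """
    if not 0.0 < quantile < 1.0:
        raise ValueError("quantile must be in (0, 1)")
    ta, ea = _group_arrays(table, group_a)
    tb, eb = _group_arrays(table, group_b)
    n_censored = int((ea == 0).sum() + (eb == 0).sum())
    if n_censored:
        log.warning("maximal-lifespan test excludes %d censored animals", n_censored)
    ta, tb = ta[ea == 1], tb[eb == 1]
    pooled = np.concatenate([ta, tb])
    if len(pooled) < 10:
        raise ValueError("fewer than 10 pooled observed lifespans; "
                         "the pooled quantile is unstable")
    threshold = _upper_order_statistic(pooled, quantile)
    counts = {
        group_a: (int((ta > threshold).sum()), len(ta)),
        group_b: (int((tb > threshold).sum()), len(tb)),
    }
    table22 = [[a, t - a] for a, t in counts.values()]
    _, p = stats.fisher_exact(table22, alternative="two-sided")
    q_a = _upper_order_statistic(ta, quantile)
    q_b = _upper_order_statistic(tb, quantile)
    return MaxLifeResult(
        threshold_age=threshold, counts=counts, p=float(p),
        group_q90={group_a: q_a, group_b: q_b},
        percent_change_q90=percent_change(q_a, q_b).raw,
        quantile=quantile, n_censored_excluded=n_censored,
    )
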