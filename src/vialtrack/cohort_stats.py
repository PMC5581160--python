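"""Cohort lifespan and group-comparison statistics.

Kaplan-Meier product-limit estimation with restricted-mean/median/maximum
lifetime summaries, two-sample log-rank tests, and per-descriptor one-way
ANOVA with Fisher's (protected) LSD pairwise t-tests at the 95% confidence
level.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

EVENT_DIED = "died"
EVENT_CENSORED = "censored"


class StatsError(ValueError):
    """Invalid survival table or comparison input."""


@dataclass
class SurvivalTable:
    """Lifespans of one group; each record is (lifespan_days, event) where
    event is 'died' or 'censored' (right censoring at last observation)."""

    group: str
    records: list[tuple[float, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        for days, event in self.records:
            if not (math.isfinite(days) and days >= 0):
                raise StatsError(f"lifespan must be finite and >= 0, got {days}")
            if event not in (EVENT_DIED, EVENT_CENSORED):
                raise StatsError(f"event must be 'died' or 'censored', got {event!r}")

    @property
    def times(self) -> np.ndarray:
        return np.array([t for t, _ in self.records], dtype=float)

    @property
    def events(self) -> np.ndarray:
        return np.array([e == EVENT_DIED for _, e in self.records], dtype=bool)

    def n_events(self) -> int:
        return int(self.events.sum())


@dataclass
class KMEstimate:
    """Product-limit survival curve: S(t) = survival[i] for
    t in [times[i], times[i+1]); S(t) = 1 before times[0]."""

    times: np.ndarray        # distinct event times, ascending
    survival: np.ndarray     # S just after each event time
    mean_lifetime: float     # restricted to the largest event time
    median_lifetime: float   # nan if the curve never reaches 0.5
    max_lifetime: float

    def survival_at(self, t: float) -> float:
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


@dataclass
class ComparisonResult:
    statistic: float
    df: float
    p_value: float
    pairwise: list[tuple[str, str, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise StatsError(f"p-value out of [0, 1]: {self.p_value}")


def km_estimate(table: SurvivalTable) -> KMEstimate:
    """Kaplan-Meier product-limit estimator with lifetime summaries.

    Median is the smallest time with S(t) <= 0.5 (nan = not reached);
    mean is the area under S(t) up to the largest event time (restricted
    mean); max is the largest observed event time.
    """
    if not table.records:
        raise StatsError(f"group {table.group!r}: empty survival table")
    times, events = table.times, table.events
    order = np.argsort(times, kind="stable")
    times, events = times[order], events[order]

    event_times = np.unique(times[events])
    if event_times.size == 0:
        # all censored: S is identically 1
        return KMEstimate(
            times=np.empty(0), survival=np.empty(0),
            mean_lifetime=math.nan, median_lifetime=math.nan,
            max_lifetime=math.nan,
        )
    surv = []
    s = 1.0
    for t in event_times:
        at_risk = int(np.sum(times >= t))
        deaths = int(np.sum((times == t) & events))
        s *= 1.0 - deaths / at_risk
        surv.append(s)
    surv_arr = np.array(surv)

    # restricted mean: area under the step function from 0 to the last event
    grid = np.concatenate(([0.0], event_times))
    heights = np.concatenate(([1.0], surv_arr[:-1]))
    mean_life = float(np.sum(np.diff(grid) * heights))

    below = np.flatnonzero(surv_arr <= 0.5)
    median = float(event_times[below[0]]) if below.size else math.nan
    return KMEstimate(
        times=event_times, survival=surv_arr,
        mean_lifetime=mean_life, median_lifetime=median,
        max_lifetime=float(event_times[-1]),
    )


def log_rank(a: SurvivalTable, b: SurvivalTable) -> ComparisonResult:
    """Two-sample log-rank chi-square (1 df) over the pooled event times."""
    if not a.records or not b.records:
        raise StatsError("log-rank needs two nonempty groups")
    if a.n_events() + b.n_events() == 0:
        raise StatsError("log-rank needs at least one death event")
    t_a, e_a, t_b, e_b = a.times, a.events, b.times, b.events
    pooled = np.unique(np.concatenate([t_a[e_a], t_b[e_b]]))

    ta_sorted = np.sort(t_a)
    tb_sorted = np.sort(t_b)
    ea_sorted = np.sort(t_a[e_a])
    eb_sorted = np.sort(t_b[e_b])
    n1 = len(t_a) - np.searchsorted(ta_sorted, pooled, side="left")
    n2 = len(t_b) - np.searchsorted(tb_sorted, pooled, side="left")
    d1 = (np.searchsorted(ea_sorted, pooled, side="right")
          - np.searchsorted(ea_sorted, pooled, side="left"))
    d2 = (np.searchsorted(eb_sorted, pooled, side="right")
          - np.searchsorted(eb_sorted, pooled, side="left"))
    n = n1 + n2
    d = d1 + d2
    ok = (n > 0) & (d > 0)
    o_minus_e = float(np.sum(d1[ok] - d[ok] * n1[ok] / n[ok]))
    vmask = ok & (n > 1)
    var = float(np.sum(
        d[vmask] * (n1[vmask] / n[vmask]) * (n2[vmask] / n[vmask])
        * (n[vmask] - d[vmask]) / (n[vmask] - 1)))
    if var == 0.0:
        return ComparisonResult(statistic=0.0, df=1, p_value=1.0)
    chi2 = o_minus_e ** 2 / var
    p = float(stats.chi2.sf(chi2, df=1))
    return ComparisonResult(statistic=float(chi2), df=1, p_value=p)


def anova_fisher_lsd(groups: Mapping[str, Sequence[float]],
                     alpha: float = 0.05) -> ComparisonResult:
    """One-way ANOVA followed by Fisher's LSD pairwise t-tests.

    The LSD tests use the pooled within-group mean square with N - k
    degrees of freedom and no multiplicity correction beyond the protection
    of a significant omnibus F. Pairwise p-values are always reported; the
    protection gate applies when interpreting them at ``alpha``.
    Degenerate all-identical input reports F = 0, p = 1 by convention.
    """
    if len(groups) < 2:
        raise StatsError("ANOVA needs at least 2 groups")
    labels = list(groups)
    arrays = {k: np.asarray(groups[k], dtype=float) for k in labels}
    for k, v in arrays.items():
        if v.size < 2:
            raise StatsError(f"group {k!r} has fewer than 2 values")
        if not np.all(np.isfinite(v)):
            raise StatsError(f"group {k!r} contains non-finite values")

    n_total = sum(v.size for v in arrays.values())
    k = len(labels)
    grand = np.concatenate(list(arrays.values())).mean()
    ss_between = sum(v.size * (v.mean() - grand) ** 2 for v in arrays.values())
    ss_within = sum(np.sum((v - v.mean()) ** 2) for v in arrays.values())
    df_between = k - 1
    df_within = n_total - k
    ms_between = ss_between / df_between
    ms_within = ss_within / df_within

    if ms_within == 0.0:
        if ms_between == 0.0:
            f_stat, p = 0.0, 1.0
        else:
            f_stat, p = math.inf, 0.0
    else:
        f_stat = ms_between / ms_within
        p = float(stats.f.sf(f_stat, df_between, df_within))

    pairwise = []
    for g1, g2 in combinations(labels, 2):
        v1, v2 = arrays[g1], arrays[g2]
        if ms_within == 0.0:
            p_pair = 1.0 if v1.mean() == v2.mean() else 0.0
        else:
            se = math.sqrt(ms_within * (1.0 / v1.size + 1.0 / v2.size))
            t = (v1.mean() - v2.mean()) / se
            p_pair = float(2.0 * stats.t.sf(abs(t), df_within))
        pairwise.append((g1, g2, p_pair))
    return ComparisonResult(
        statistic=float(f_stat) if math.isfinite(f_stat) else math.inf,
        df=df_between, p_value=p, pairwise=pairwise,
    )


def significant_pairs(result: ComparisonResult, alpha: float = 0.05
                      ) -> list[tuple[str, str, float]]:
    """Fisher-protected significant pairs: none unless the omnibus test is
    itself significant at ``alpha``."""
    if result.p_value >= alpha:
        return []
    return [(a, b, p) for a, b, p in result.pairwise if p < alpha]


def read_survival_csv(path: str | Path) -> dict[str, SurvivalTable]:
    """Read a lifespan CSV with header ``group,lifespan_days,event``."""
    p = Path(path)
    df = pd.read_csv(p)
    expected = ["group", "lifespan_days", "event"]
    missing = [c for c in expected if c not in df.columns]
    if missing:
        raise StatsError(f"{p}: missing column(s) {missing}")
    tables: dict[str, SurvivalTable] = {}
    for g, sub in df.groupby("group", sort=True):
        records = [(float(r.lifespan_days), str(r.event))
                   for r in sub.itertuples(index=False)]
        tables[str(g)] = SurvivalTable(group=str(g), records=records)
    return tables
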