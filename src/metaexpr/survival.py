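"""Kaplan–Meier estimation, log-rank test and Peto hazard ratio.

The marker (log2 expression) is dichotomized at the cohort median; overall
survival of the high-expression group is compared with the low group by the
log-rank test over pooled event times, and the hazard ratio comes from the
Peto one-step estimator lnHR = (O − E)/V. Ties at one time are processed
events-first (the standard product-limit convention).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

Z95 = 1.96


@dataclass
class SurvivalTable:
    """Rows of (sample_id, time in months, event 1/0, marker expression)."""

    data: pd.DataFrame  # columns: sample_id, time, event, marker

    def __post_init__(self) -> None:
        required = {"sample_id", "time", "event", "marker"}
        missing = required - set(self.data.columns)
        if missing:
            raise ValueError(f"survival table missing columns: {sorted(missing)}")
        if (self.data["time"] <= 0).any():
            raise ValueError("survival times must be positive")
        if not self.data["event"].isin([0, 1]).all():
            raise ValueError("event must be 0 (censored) or 1 (death)")

    @classmethod
    def read(cls, path: str | Path) -> "SurvivalTable":
        return cls(pd.read_csv(path, sep="\t"))

    def write(self, path: str | Path) -> None:
        self.data.to_csv(path, sep="\t", index=False)


@dataclass(frozen=True)
class LogrankResult:
    chi2: float
    p: float
    hr: float  # hazard of the high-marker group relative to low
    ci95: tuple[float, float]
    o_minus_e: float
    var: float


def dichotomize(table: SurvivalTable, rule: str = "median") -> pd.Series:
    """Label each sample high/low by the marker median.

    The median is the lower of the two middle order statistics for even n, and
    samples with marker ≥ median go to the high group — both groups are then
    non-empty and the split is deterministic.
    """
    if rule != "median":
        raise ValueError(f"unknown dichotomization rule: {rule}")
    marker = table.data["marker"].values.astype(float)
    if len(marker) < 4:
        raise ValueError("need at least 4 samples to dichotomize")
    if np.ptp(marker) == 0:
        raise ValueError("degenerate split: all marker values equal")
    med = float(np.sort(marker)[(len(marker) - 1) // 2])  # lower middle
    labels = np.where(marker >= med, "high", "low")
    if (labels == "low").sum() == 0:
        # median equals the minimum (repeated low values): put strict-minimum
        # samples low is impossible, so move the ≥-tied minimum samples low
        labels = np.where(marker > med, "high", "low")
    if (labels == "high").sum() == 0 or (labels == "low").sum() == 0:
        raise ValueError("degenerate split: one group empty")
    return pd.Series(labels, index=table.data["sample_id"].values)


def km_estimate(times, events) -> pd.DataFrame:
    """Product-limit survival estimate.

    Returns one row per distinct event time: (time, at_risk, events,
    survival). Censored-only data yield S(t) ≡ 1 (empty table).
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if len(times) == 0:
        raise ValueError("need at least one subject")
    order = np.argsort(times, kind="stable")
    times, events = times[order], events[order]
    rows = []
    s = 1.0
    for t in np.unique(times[events == 1]):
        at_risk = int((times >= t).sum())  # events before censorings at ties
        d = int(((times == t) & (events == 1)).sum())
        s *= 1.0 - d / at_risk
        rows.append({"time": float(t), "at_risk": at_risk, "events": d,
                     "survival": s})
    return pd.DataFrame(rows, columns=["time", "at_risk", "events", "survival"])


def logrank_hr(times_high, events_high, times_low, events_low) -> LogrankResult:
    """Log-rank test and Peto hazard ratio, high vs low group.

    At each pooled event time the observed high-group events are compared
    with their hypergeometric expectation; chi² = (O−E)²/V on 1 df, and
    lnHR = (O−E)/V with var(lnHR) = 1/V (Peto's one-step estimator).
    """
    th = np.asarray(times_high, dtype=float)
    eh = np.asarray(events_high, dtype=int)
    tl = np.asarray(times_low, dtype=float)
    el = np.asarray(events_low, dtype=int)
    if eh.sum() + el.sum() == 0:
        raise ValueError("no events in either group")
    all_times = np.concatenate([th, tl])
    all_events = np.concatenate([eh, el])
    in_high = np.concatenate([np.ones(len(th), bool), np.zeros(len(tl), bool)])

    o_minus_e = 0.0
    v = 0.0
    for t in np.unique(all_times[all_events == 1]):
        at_risk = all_times >= t
        n = int(at_risk.sum())
        n_high = int((at_risk & in_high).sum())
        d = int(((all_times == t) & (all_events == 1)).sum())
        d_high = int(((all_times == t) & (all_events == 1) & in_high).sum())
        e_high = d * n_high / n
        o_minus_e += d_high - e_high
        if n > 1:
            v += d * (n_high / n) * (1 - n_high / n) * (n - d) / (n - 1)
    if v <= 0:
        raise ValueError("no information: log-rank variance is zero")
    chi2 = o_minus_e**2 / v
    p = float(stats.chi2.sf(chi2, 1))
    ln_hr = o_minus_e / v
    se = 1.0 / math.sqrt(v)
    return LogrankResult(chi2=float(chi2), p=p, hr=math.exp(ln_hr),
                         ci95=(math.exp(ln_hr - Z95 * se),
                               math.exp(ln_hr + Z95 * se)),
                         o_minus_e=float(o_minus_e), var=float(v))


@dataclass(frozen=True)
class KMResult:
    """Per-group survival curves plus the log-rank/HR comparison."""

    km_high: pd.DataFrame
    km_low: pd.DataFrame
    logrank: LogrankResult
    n_high: int
    n_low: int


def analyze(table: SurvivalTable) -> KMResult:
    """Median-split the marker, estimate KM per group, test and report HR."""
    groups = dichotomize(table)
    df = table.data.set_index("sample_id")
    high = df.loc[groups[groups == "high"].index]
    low = df.loc[groups[groups == "low"].index]
    res = logrank_hr(high["time"], high["event"], low["time"], low["event"])
    return KMResult(
        km_high=km_estimate(high["time"], high["event"]),
        km_low=km_estimate(low["time"], low["event"]),
        logrank=res,
        n_high=len(high),
        n_low=len(low),
    )
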