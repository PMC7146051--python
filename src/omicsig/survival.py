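"""Kaplan–Meier estimation and the two-group log-rank test.

Both are implemented directly from the product-limit and hypergeometric
definitions (the package's survival comparisons are a first-class output,
cross-checked against lifelines in the test suite).  Tie convention:
deaths at a time t are processed before censorings at the same t, i.e. a
subject censored at t is still at risk for the deaths at t.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class KMCurve:
    """Product-limit survival estimate at the distinct event times."""

    event_times: np.ndarray   # distinct times with >= 1 death
    at_risk: np.ndarray       # n_i just before each event time
    events: np.ndarray        # d_i deaths at each event time
    survival: np.ndarray      # Ŝ(t_i)

    def survival_at(self, t: float) -> float:
        """Step-function value Ŝ(t); Ŝ(0) = 1."""
        idx = np.searchsorted(self.event_times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "time": self.event_times,
            "n_risk": self.at_risk,
            "n_event": self.events,
            "survival": self.survival,
        })


def _check_times(times, events) -> tuple[np.ndarray, np.ndarray]:
    times = np.asarray(times, dtype=float)
    events = np.asarray(events)
    if times.ndim != 1 or events.shape != times.shape:
        raise ValueError("times and events must be matching 1-D arrays")
    if np.any(times < 0) or np.any(~np.isfinite(times)):
        raise ValueError("times must be finite and >= 0")
    if not np.isin(events, [0, 1]).all():
        raise ValueError("events must be binary 0/1")
    return times, events.astype(int)


def km_estimate(times, events) -> KMCurve:
    """Kaplan–Meier estimate Ŝ(t) = Π_{t_i ≤ t} (1 − d_i/n_i).

    Censored-only times reduce the risk set but contribute no factor.
    """
    times, events = _check_times(times, events)
    order = np.lexsort((1 - events, times))  # deaths before censorings at ties
    t_sorted = times[order]
    e_sorted = events[order]
    n = len(times)

    event_times, at_risk, deaths = [], [], []
    i = 0
    n_risk = n
    while i < n:
        t = t_sorted[i]
        d = 0
        c = 0
        while i < n and t_sorted[i] == t:
            if e_sorted[i] == 1:
                d += 1
            else:
                c += 1
            i += 1
        if d > 0:
            event_times.append(t)
            at_risk.append(n_risk)
            deaths.append(d)
        n_risk -= d + c
    surv = np.cumprod(1.0 - np.asarray(deaths, dtype=float)
                      / np.asarray(at_risk, dtype=float)) if deaths else np.array([])
    return KMCurve(np.asarray(event_times, dtype=float),
                   np.asarray(at_risk, dtype=int),
                   np.asarray(deaths, dtype=int), surv)


def logrank_test(times, events, group_labels) -> tuple[float, float]:
    """Two-group log-rank test; returns (chi-square statistic, p-value).

    At each distinct death time j with d_j total deaths among n_j at risk
    (n_1j in group 1), the observed O_1j is compared with the
    hypergeometric expectation E_1j = d_j·n_1j/n_j and variance
    V_j = d_j·(n_1j/n_j)·(1 − n_1j/n_j)·(n_j − d_j)/(n_j − 1); the
    statistic (ΣO − ΣE)²/ΣV is referred to χ²(1).
    """
    times, events = _check_times(times, events)
    group_labels = np.asarray(group_labels)
    levels = np.unique(group_labels)
    if len(levels) != 2:
        raise ValueError(f"exactly two groups required, got {list(levels)}")
    g1 = group_labels == levels[0]

    death_times = np.unique(times[events == 1])
    o_minus_e = 0.0
    var_sum = 0.0
    for t in death_times:
        at_risk = times >= t
        n_j = int(at_risk.sum())
        n_1j = int((at_risk & g1).sum())
        d_j = int(((times == t) & (events == 1)).sum())
        o_1j = int(((times == t) & (events == 1) & g1).sum())
        e_1j = d_j * n_1j / n_j
        o_minus_e += o_1j - e_1j
        if n_j > 1:
            var_sum += (d_j * (n_1j / n_j) * (1 - n_1j / n_j)
                        * (n_j - d_j) / (n_j - 1))
    if var_sum == 0:
        return 0.0, 1.0
    chi_sq = o_minus_e ** 2 / var_sum
    p = float(stats.chi2.sf(chi_sq, df=1))
    return float(chi_sq), p


def write_km_curve(curve: KMCurve, path) -> None:
    curve.to_frame().to_csv(path, sep="\t", index=False, float_format="%.10g")
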