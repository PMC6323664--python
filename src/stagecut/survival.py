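"""Kaplan-Meier estimation and log-rank tests from their defining formulas.

The cut-point scan ranks every candidate MLN cutoff by the magnitude of
the two-group log-rank chi-square, so the statistic itself — risk-set
bookkeeping, tie handling, the hypergeometric variance and its guards —
is authored here rather than delegated to a fitting library.  An
established survival package serves only as an independent cross-check
in the test suite.

Conventions (standard, and stated once):

* a subject censored exactly at an event time is still at risk for that
  event time;
* five-year overall survival is S(t) evaluated at t = 60 months with the
  right-continuous step convention;
* at a pooled event time with a risk set of a single subject the
  hypergeometric variance term is zero (the formula's n-1 denominator
  vanishes);
* p-values come from the upper tail of the chi-square distribution with
  no continuity correction.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import chi2 as _chi2_dist


@dataclass
class KMCurve:
    """Product-limit survival estimate, tabulated at distinct event times."""

    event_times: np.ndarray   # strictly increasing, months
    n_at_risk: np.ndarray     # at risk just before each event time
    n_events: np.ndarray      # deaths at each event time
    survival: np.ndarray      # S(t) at each event time (right-continuous)
    n_total: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "time": self.event_times,
            "n_at_risk": self.n_at_risk,
            "n_events": self.n_events,
            "survival": self.survival,
        })

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


@dataclass
class LogRankResult:
    chi2: float
    df: int
    p_value: float
    group_sizes: tuple[int, ...]
    observed: np.ndarray
    expected: np.ndarray


def _as_time_event(times, events) -> tuple[np.ndarray, np.ndarray]:
    t = np.asarray(times, dtype=float)
    e = np.asarray(events)
    if t.ndim != 1 or e.shape != t.shape:
        raise ValueError("times and events must be equal-length 1-d arrays")
    if t.size == 0:
        raise ValueError("empty survival input")
    if np.any(t < 0) or np.any(np.isnan(t)):
        raise ValueError("times must be finite and >= 0")
    e = e.astype(float)
    if not np.all(np.isin(e, (0.0, 1.0))):
        raise ValueError("events must be 0/1")
    return t, e.astype(int)


def km_fit(times, events) -> KMCurve:
    """Kaplan-Meier product-limit fit.

    S(t) = prod over event times t_i <= t of (1 - d_i / n_i), where d_i
    is the number of deaths at t_i and n_i the number still at risk
    (subjects with follow-up >= t_i, including those censored at t_i).
    """
    t, e = _as_time_event(times, events)
    order = np.argsort(t, kind="stable")
    ts, es = t[order], e[order]
    n = ts.size
    death_times = ts[es == 1]
    event_times = np.unique(death_times)
    if event_times.size == 0:
        return KMCurve(event_times=np.empty(0), n_at_risk=np.empty(0, int),
                       n_events=np.empty(0, int),
                       survival=np.empty(0), n_total=n)
    n_at_risk = n - np.searchsorted(ts, event_times, side="left")
    d = (np.searchsorted(death_times, event_times, side="right")
         - np.searchsorted(death_times, event_times, side="left"))
    surv = np.cumprod(1.0 - d / n_at_risk)
    return KMCurve(event_times=event_times, n_at_risk=n_at_risk.astype(int),
                   n_events=d.astype(int), survival=surv, n_total=n)


def survival_at(curve: KMCurve, t: float) -> float:
    """S(t) under the step convention: the estimate at the largest event
    time <= t; 1.0 before the first event; the last estimate beyond the
    final event time (no extrapolation error is raised)."""
    if t < 0:
        raise ValueError("t must be >= 0")
    if curve.event_times.size == 0:
        return 1.0
    i = np.searchsorted(curve.event_times, t, side="right")
    return 1.0 if i == 0 else float(curve.survival[i - 1])


def logrank(groups: Sequence[tuple]) -> LogRankResult:
    """k-group log-rank test (df = k-1).

    At each pooled distinct event time t_j with d_j total deaths among
    n_j at risk, group g contributes observed deaths d_gj and expected
    n_gj * d_j / n_j.  The covariance of the observed-death vector sums
    d_j (n_j - d_j)/(n_j - 1) * [diag(w) - w w'] with w_g = n_gj / n_j
    (zero when n_j = 1), and the statistic is the quadratic form over
    the first k-1 groups.  For k = 2 this reduces to the familiar
    (sum(O1 - E1))^2 / sum(V_j) with
    V_j = n_1j n_2j d_j (n_j - d_j) / (n_j^2 (n_j - 1)).

    Zero total events is a documented degenerate result (chi2 = 0,
    p = 1), not an error; an empty group is an error.
    """
    if len(groups) < 2:
        raise ValueError("logrank needs >= 2 groups")
    parsed = []
    for g, (times, events) in enumerate(groups):
        t, e = np.asarray(times, float), np.asarray(events)
        if t.size == 0:
            raise ValueError(f"group {g} has zero subjects")
        parsed.append(_as_time_event(t, e))
    k = len(parsed)
    sizes = tuple(t.size for t, _ in parsed)

    all_death_times = np.concatenate([t[e == 1] for t, e in parsed])
    taus = np.unique(all_death_times)
    if taus.size == 0:
        zeros = np.zeros(k)
        return LogRankResult(chi2=0.0, df=k - 1, p_value=1.0,
                             group_sizes=sizes, observed=zeros,
                             expected=zeros)

    T = taus.size
    n_gj = np.empty((k, T))
    d_gj = np.empty((k, T))
    for g, (t, e) in enumerate(parsed):
        ts = np.sort(t)
        n_gj[g] = t.size - np.searchsorted(ts, taus, side="left")
        dt = np.sort(t[e == 1])
        d_gj[g] = (np.searchsorted(dt, taus, side="right")
                   - np.searchsorted(dt, taus, side="left"))
    n_j = n_gj.sum(axis=0)
    d_j = d_gj.sum(axis=0)

    E_gj = n_gj * d_j / n_j
    observed = d_gj.sum(axis=1)
    expected = E_gj.sum(axis=1)

    with np.errstate(divide="ignore", invalid="ignore"):
        c_j = np.where(n_j > 1, d_j * (n_j - d_j) / (n_j - 1.0), 0.0)
    w = n_gj / n_j                                     # (k, T)
    # V = sum_j c_j (diag(w_j) - w_j w_j'), restricted to first k-1 groups
    m = k - 1
    wm = w[:m]
    V = np.einsum("j,gj,hj->gh", c_j, wm, wm) * -1.0
    V[np.arange(m), np.arange(m)] += (c_j * wm).sum(axis=1)
    z = (observed - expected)[:m]
    try:
        chi2 = float(z @ np.linalg.solve(V, z))
    except np.linalg.LinAlgError:
        chi2 = float(z @ np.linalg.pinv(V) @ z)
    chi2 = max(chi2, 0.0)
    p = float(_chi2_dist.sf(chi2, k - 1))
    return LogRankResult(chi2=chi2, df=k - 1, p_value=p, group_sizes=sizes,
                         observed=observed, expected=expected)


def plot_km(curves: Mapping[str, KMCurve], path, xlabel: str = "Months",
            ylabel: str = "Overall survival") -> None:
    """Step-plot one or more KM curves to an image file."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4.5))
    for label, curve in curves.items():
        x = np.r_[0.0, curve.event_times]
        y = np.r_[1.0, curve.survival]
        ax.step(x, y, where="post", label=label)
    ax.set_xlabel(xlabel)
    ax.set_ylabel(ylabel)
    ax.set_ylim(0, 1.02)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
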