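"""Independent brute-force oracles and record factories for the tests.

Everything here is deliberately written as plain loops over the defining
formulas, independent of the vectorized implementation paths it checks.
"""
from __future__ import annotations

import math

import numpy as np

from stagecut import Cohort, PatientRecord


def make_record(i: int = 0, **kw) -> PatientRecord:
    """A valid eligible record; override any field by keyword."""
    base = dict(
        id=f"P{i:05d}", source="SYNTH", age_years=60, sex="male",
        ethnicity="asian", histology_grade="G3_G4", tumor_size_mm=60.0,
        pt_category="T3", m_category="M0", lns_examined=30, mln_count=12,
        surgery="partial_gastrectomy", followup_months=24.0, event=1,
        primary_site_stomach=True, adenocarcinoma=True,
        multiple_primaries=False, remnant_gastric=False,
    )
    base.update(kw)
    return PatientRecord(**base)


def make_cohort(records, provenance="test") -> Cohort:
    return Cohort.from_records(records, provenance=provenance)


def cohort_from_arrays(times, events, mln=None, pt=None, **kw) -> Cohort:
    """Small survival-only cohort with optional MLN counts / pT labels."""
    n = len(times)
    mln = [12] * n if mln is None else mln
    pt = ["T3"] * n if pt is None else pt
    recs = [make_record(i, followup_months=float(times[i]),
                        event=int(events[i]), mln_count=int(mln[i]),
                        lns_examined=max(30, int(mln[i]) + 1),
                        pt_category=pt[i], **kw)
            for i in range(n)]
    return make_cohort(recs)


# ---------------------------------------------------------------------------
# Brute-force oracles
# ---------------------------------------------------------------------------

def brute_km(times, events):
    """Product-limit estimate by direct counting: list of (t, S(t))."""
    times = [float(t) for t in times]
    events = [int(e) for e in events]
    taus = sorted({t for t, e in zip(times, events) if e == 1})
    out = []
    s = 1.0
    for tau in taus:
        n_at_risk = sum(1 for t in times if t >= tau)
        d = sum(1 for t, e in zip(times, events) if e == 1 and t == tau)
        s *= 1.0 - d / n_at_risk
        out.append((tau, s))
    return out


def brute_logrank_2group(g1, g2):
    """Two-group log-rank chi-square by direct O/E/V summation."""
    (t1, e1), (t2, e2) = g1, g2
    t1 = [float(x) for x in t1]; t2 = [float(x) for x in t2]
    e1 = [int(x) for x in e1]; e2 = [int(x) for x in e2]
    taus = sorted({t for t, e in zip(list(t1) + list(t2),
                                     list(e1) + list(e2)) if e == 1})
    oe = 0.0
    v = 0.0
    for tau in taus:
        n1 = sum(1 for t in t1 if t >= tau)
        n2 = sum(1 for t in t2 if t >= tau)
        d1 = sum(1 for t, e in zip(t1, e1) if e == 1 and t == tau)
        d2 = sum(1 for t, e in zip(t2, e2) if e == 1 and t == tau)
        n = n1 + n2
        d = d1 + d2
        oe += d1 - n1 * d / n
        if n > 1:
            v += n1 * n2 * d * (n - d) / (n ** 2 * (n - 1))
    return 0.0 if v == 0 else oe ** 2 / v


def brute_logrank_kgroup(groups):
    """k-group log-rank chi-square via the vector-variance form with
    explicit loops."""
    k = len(groups)
    parsed = [([float(x) for x in t], [int(x) for x in e])
              for t, e in groups]
    taus = sorted({t for ts, es in parsed
                   for t, e in zip(ts, es) if e == 1})
    z = np.zeros(k - 1)
    V = np.zeros((k - 1, k - 1))
    for tau in taus:
        ns = [sum(1 for t in ts if t >= tau) for ts, _ in parsed]
        ds = [sum(1 for t, e in zip(ts, es) if e == 1 and t == tau)
              for ts, es in parsed]
        n, d = sum(ns), sum(ds)
        for g in range(k - 1):
            z[g] += ds[g] - ns[g] * d / n
        if n > 1:
            c = d * (n - d) / (n - 1)
            for g in range(k - 1):
                for h in range(k - 1):
                    w_g, w_h = ns[g] / n, ns[h] / n
                    V[g, h] += c * (w_g * (1 - w_g) if g == h
                                    else -w_g * w_h)
    return float(z @ np.linalg.solve(V, z))


def brute_cox_loglik(beta, X, times, events, ties="breslow"):
    """Partial log-likelihood evaluated by direct risk-set loops."""
    beta = np.asarray(beta, float)
    X = np.asarray(X, float)
    if X.ndim == 1:
        X = X[:, None]
    t = [float(x) for x in times]
    e = [int(x) for x in events]
    eta = [float(X[i] @ beta) for i in range(len(t))]
    taus = sorted({t[i] for i in range(len(t)) if e[i]})
    ll = 0.0
    for tau in taus:
        D = [i for i in range(len(t)) if e[i] and t[i] == tau]
        R = [i for i in range(len(t)) if t[i] >= tau]
        s_r = sum(math.exp(eta[i]) for i in R)
        s_d = sum(math.exp(eta[i]) for i in D)
        ll += sum(eta[i] for i in D)
        m = len(D)
        if ties == "breslow":
            ll -= m * math.log(s_r)
        else:
            ll -= sum(math.log(s_r - (l / m) * s_d) for l in range(m))
    return ll
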