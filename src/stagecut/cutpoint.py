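"""Maximal log-rank cut-point scan over candidate MLN cutoffs.

Every candidate cutoff c splits the N3 cohort into "<= c" and "> c"
metastatic-node groups; the scan records each split's two-group log-rank
chi-square, p-value and five-year overall survival, and selects the
cutoff with the largest chi-square (ties broken toward the smallest
cutoff).  No multiplicity correction is applied to the selected
cutoff's p-value; the null distribution of the maximum is inflated
relative to a single fixed test, and the test suite documents that
inflation rather than adjusting for it.

The three-band analysis re-examines the patients the modified split
reassigns (e.g. 14-15 metastatic nodes): per-band KM curves and all
pairwise log-rank tests with unadjusted p-values.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Union

import numpy as np
import pandas as pd

from .cohort import Cohort
from .survival import KMCurve, km_fit, logrank, survival_at

__all__ = ["CutpointRow", "CutpointScanResult", "ThreeBandReport",
           "scan", "three_band_analysis"]


@dataclass
class CutpointRow:
    cutoff: int
    n_low: int          # mln_count <= cutoff
    n_high: int
    os5_low: float      # five-year OS, fraction in [0, 1]
    os5_high: float
    chi2: float
    p_value: float


@dataclass
class CutpointScanResult:
    rows: list[CutpointRow]
    selected_cutoff: int
    selection_chi2: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([{
            "cutoff": r.cutoff,
            "n_low": r.n_low, "n_high": r.n_high,
            "os5_low_pct": 100.0 * r.os5_low,
            "os5_high_pct": 100.0 * r.os5_high,
            "chi2": r.chi2, "p_value": r.p_value,
            "selected": r.cutoff == self.selected_cutoff,
        } for r in self.rows])

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def _time_event(data: Union[Cohort, pd.DataFrame]):
    df = data.df if isinstance(data, Cohort) else data
    mln = df["mln_count"].to_numpy(float)
    if np.isnan(mln).any() or (mln < 7).any():
        raise ValueError("scan requires a screened N3 cohort "
                         "(all mln_count present and >= 7)")
    return (mln.astype(int), df["followup_months"].to_numpy(float),
            df["event"].to_numpy(float))


def scan(data: Union[Cohort, pd.DataFrame],
         cutoff_range: tuple[int, int] = (7, 20),
         min_group: int = 20) -> CutpointScanResult:
    """Evaluate every candidate cutoff and select the chi-square maximum.

    Cutoffs whose low or high group holds fewer than ``min_group``
    subjects are skipped (the chi-square degenerates for tiny groups);
    if no cutoff is admissible a ValueError names the constraint.
    """
    mln, t, e = _time_event(data)
    lo, hi = int(cutoff_range[0]), int(cutoff_range[1])
    if lo > hi:
        raise ValueError("empty cutoff range")
    rows: list[CutpointRow] = []
    for c in range(lo, hi + 1):
        mask = mln <= c
        n_low, n_high = int(mask.sum()), int((~mask).sum())
        if n_low < min_group or n_high < min_group:
            continue
        lr = logrank([(t[mask], e[mask]), (t[~mask], e[~mask])])
        rows.append(CutpointRow(
            cutoff=c, n_low=n_low, n_high=n_high,
            os5_low=survival_at(km_fit(t[mask], e[mask]), 60.0),
            os5_high=survival_at(km_fit(t[~mask], e[~mask]), 60.0),
            chi2=lr.chi2, p_value=lr.p_value))
    if not rows:
        raise ValueError(
            f"no admissible cutoff in [{lo}, {hi}]: every split leaves "
            f"a group below min_group={min_group}")
    best = rows[0]
    for r in rows[1:]:
        if r.chi2 > best.chi2:     # strict: ties keep the smallest cutoff
            best = r
    return CutpointScanResult(rows=rows, selected_cutoff=best.cutoff,
                              selection_chi2=best.chi2)


@dataclass
class ThreeBandReport:
    """Survival of the low / reassigned-middle / high MLN bands."""

    bands: dict[str, tuple[int, int]]          # label -> inclusive interval
    n: dict[str, int]
    os5: dict[str, float]
    km: dict[str, KMCurve]
    pairwise: dict[str, dict]                  # "low_vs_mid" etc.

    def to_frame(self) -> pd.DataFrame:
        band_rows = [{
            "band": label,
            "mln_from": self.bands[label][0],
            "mln_to": self.bands[label][1],
            "n": self.n[label],
            "os5_pct": 100.0 * self.os5[label],
        } for label in ("low", "mid", "high")]
        return pd.DataFrame(band_rows)

    def pairwise_frame(self) -> pd.DataFrame:
        return pd.DataFrame([{"comparison": k, **v}
                             for k, v in self.pairwise.items()])


def three_band_analysis(data: Union[Cohort, pd.DataFrame],
                        low_band: tuple[int, int] = (7, 13),
                        mid_band: tuple[int, int] = (14, 15)
                        ) -> ThreeBandReport:
    """KM curves, five-year OS and pairwise log-rank tests for the bands
    low, mid (the patients the modified split reassigns) and high
    (> mid_band upper bound).  The bands must partition the MLN range."""
    mln, t, e = _time_event(data)
    lo = (int(low_band[0]), int(low_band[1]))
    mid = (int(mid_band[0]), int(mid_band[1]))
    if not (lo[0] <= lo[1] and mid[0] <= mid[1] and mid[0] == lo[1] + 1):
        raise ValueError("bands must be contiguous ordered intervals")
    if lo[0] > int(mln.min()):
        raise ValueError("low band does not cover the smallest MLN count")
    bands = {"low": lo, "mid": mid, "high": (mid[1] + 1, int(mln.max()))}
    masks = {
        "low": (mln >= lo[0]) & (mln <= lo[1]),
        "mid": (mln >= mid[0]) & (mln <= mid[1]),
        "high": mln > mid[1],
    }
    n = {k: int(m.sum()) for k, m in masks.items()}
    for k, cnt in n.items():
        if cnt == 0:
            raise ValueError(f"band {k!r} {bands[k]} is empty")
    km = {k: km_fit(t[m], e[m]) for k, m in masks.items()}
    os5 = {k: survival_at(km[k], 60.0) for k in masks}
    pairwise = {}
    for a, b in (("low", "mid"), ("mid", "high"), ("low", "high")):
        lr = logrank([(t[masks[a]], e[masks[a]]),
                      (t[masks[b]], e[masks[b]])])
        pairwise[f"{a}_vs_{b}"] = {"chi2": lr.chi2, "df": lr.df,
                                   "p_value": lr.p_value}
    return ThreeBandReport(bands=bands, n=n, os5=os5, km=km,
                           pairwise=pairwise)
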