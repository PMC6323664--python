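"""N3 subclassification and TNM stage grouping.

Two systems share one (pT, N subcategory) -> stage table, stored as a
versioned YAML resource so alternative editions can be swapped in:

* ``eighth``   — N3a for 7-15 metastatic nodes, N3b for > 15;
* ``modified`` — the same grouping with the boundary moved (default 13,
  i.e. mN3a 7-13, mN3b > 13, so patients with 14-15 metastatic nodes
  are upstaged into mN3b).
"""
from __future__ import annotations

from dataclasses import dataclass
from importlib import resources as _resources
from typing import Mapping, Union

import numpy as np
import pandas as pd
import yaml

from .cohort import Cohort
from .survival import KMCurve, km_fit, survival_at

STAGE_ORDER = ("IIB", "IIIA", "IIIB", "IIIC")
EIGHTH_CUTOFF = 15
MODIFIED_DEFAULT_CUTOFF = 13

_PT_ORDER = ("T1", "T2", "T3", "T4a", "T4b")


@dataclass(frozen=True)
class NSubcategory:
    label: str          # "N3a" | "N3b"
    system: str         # "eighth" | "modified"

    @property
    def display(self) -> str:
        return ("m" + self.label) if self.system == "modified" else self.label


@dataclass(frozen=True)
class StagingSystem:
    """An ordered (pT, N subcategory) -> stage mapping, parameterized by
    the N3a/N3b boundary."""

    name: str
    cutoff: int
    grouping: Mapping[str, Mapping[str, str]]
    stage_order: tuple[str, ...] = STAGE_ORDER

    def __post_init__(self) -> None:
        rank = {s: i for i, s in enumerate(self.stage_order)}
        prev_a = prev_b = -1
        for pt in _PT_ORDER:
            cell = self.grouping.get(pt)
            if cell is None or set(cell) != {"N3a", "N3b"}:
                raise ValueError(f"grouping must cover (pT={pt}, N3a/N3b)")
            a, b = rank[cell["N3a"]], rank[cell["N3b"]]
            if b < a:
                raise ValueError(f"stage decreases N3a->N3b at {pt}")
            if a < prev_a or b < prev_b:
                raise ValueError(f"stage decreases with advancing pT at {pt}")
            prev_a, prev_b = a, b

    @classmethod
    def eighth(cls) -> "StagingSystem":
        text = (_resources.files("stagecut.resources")
                / "staging_eighth_n3.yaml").read_text()
        spec = yaml.safe_load(text)
        return cls(name=spec["name"], cutoff=int(spec["n3a_n3b_cutoff"]),
                   grouping=spec["grouping"],
                   stage_order=tuple(spec["stage_order"]))

    @classmethod
    def modified(cls, cutoff: int = MODIFIED_DEFAULT_CUTOFF) -> "StagingSystem":
        base = cls.eighth()
        return cls(name="modified", cutoff=int(cutoff),
                   grouping=base.grouping, stage_order=base.stage_order)


def _as_system(system: Union[str, StagingSystem]) -> StagingSystem:
    if isinstance(system, StagingSystem):
        return system
    if system == "eighth":
        return StagingSystem.eighth()
    if system == "modified":
        return StagingSystem.modified()
    raise ValueError(f"unknown staging system {system!r}")


def assign_n(mln_count: int, system: Union[str, StagingSystem]) -> NSubcategory:
    """N3a/N3b subcategory of an MLN count under the given system."""
    sys_ = _as_system(system)
    if mln_count < 7:
        raise ValueError(
            f"mln_count={mln_count} is not N3 disease (requires >= 7)")
    label = "N3b" if mln_count > sys_.cutoff else "N3a"
    return NSubcategory(label=label, system=sys_.name)


def stage_group(pt: str, n: Union[str, NSubcategory],
                system: Union[str, StagingSystem, None] = None) -> str:
    """Final pathological stage of an M0/N3 tumor."""
    sys_ = _as_system(system) if system is not None else (
        _as_system(n.system) if isinstance(n, NSubcategory)
        else StagingSystem.eighth())
    label = n.label if isinstance(n, NSubcategory) else str(n).lstrip("m")
    if pt not in _PT_ORDER:
        raise ValueError(f"pT category {pt!r} outside T1..T4b")
    if label not in ("N3a", "N3b"):
        raise ValueError(f"N subcategory {label!r} must be N3a or N3b")
    return sys_.grouping[pt][label]


@dataclass
class RestagedCohort:
    """A cohort with per-record N subcategory and stage labels plus
    per-stage counts, 5-year OS and KM curves (empty stages keep count
    0 and are never dropped)."""

    cohort: Cohort
    system: StagingSystem
    counts: dict[str, int]
    os5: dict[str, float]
    km: dict[str, KMCurve]

    def counts_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "stage": list(self.system.stage_order),
            "n": [self.counts[s] for s in self.system.stage_order],
            "os5_pct": [100.0 * self.os5[s] if s in self.os5 else np.nan
                        for s in self.system.stage_order],
        })


def restage_cohort(cohort: Cohort,
                   system: Union[str, StagingSystem]) -> RestagedCohort:
    """Label every record with its N subcategory and stage under the
    system; returns per-stage counts, 5-year OS and KM curves."""
    sys_ = _as_system(system)
    df = cohort.df.copy()
    mln = df["mln_count"].to_numpy(float)
    if np.isnan(mln).any() or (mln < 7).any():
        raise ValueError("restaging requires a screened N3 cohort "
                         "(all mln_count present and >= 7)")
    labels = np.where(mln > sys_.cutoff, "N3b", "N3a")
    prefix = "m" if sys_.name == "modified" else ""
    df["n_sub"] = prefix + pd.Series(labels, index=df.index)
    stage = np.empty(len(df), dtype=object)
    for pt in _PT_ORDER:
        for nl in ("N3a", "N3b"):
            sel = (df["pt_category"] == pt).to_numpy() & (labels == nl)
            stage[sel] = sys_.grouping[pt][nl]
    bad = (~df["pt_category"].isin(_PT_ORDER)).to_numpy()
    if bad.any():
        raise ValueError("restaging requires pt_category in T1..T4b")
    df["stage"] = stage

    t = df["followup_months"].to_numpy(float)
    e = df["event"].to_numpy(float)
    counts, os5, km = {}, {}, {}
    for s in sys_.stage_order:
        mask = (df["stage"] == s).to_numpy()
        counts[s] = int(mask.sum())
        if counts[s]:
            curve = km_fit(t[mask], e[mask])
            km[s] = curve
            os5[s] = survival_at(curve, 60.0)
    staged = Cohort(df, provenance=f"{cohort.provenance} "
                                   f"[staged:{sys_.name}]".strip(),
                    attrs=dict(cohort.attrs))
    return RestagedCohort(cohort=staged, system=sys_, counts=counts,
                          os5=os5, km=km)
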