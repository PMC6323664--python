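"""Cohort data model, CSV I/O, eligibility screening, and demographic summaries.

The unit of analysis is one gastrectomy patient with pathologically
node-positive (pN3, i.e. >= 7 metastatic lymph nodes) gastric
adenocarcinoma.  A :class:`Cohort` wraps a pandas DataFrame in a fixed
CSV schema; :func:`screen_cohort` applies registry-style eligibility
criteria in a fixed, documented order; :func:`summarize` produces a
demographics table with between-source chi-square / Mann-Whitney
comparisons.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as _stats

SOURCES = ("SEER", "FMUUH", "SYNTH")
SEXES = ("male", "female")
ETHNICITIES = ("white", "asian", "black", "hispanic", "native_american", "other")
GRADES = ("G1_G2", "G3_G4", "other")
PT_CATEGORIES = ("T1", "T2", "T3", "T4a", "T4b", "other")
M_CATEGORIES = ("M0", "M1", "unknown")
SURGERIES = ("partial_gastrectomy", "total_gastrectomy", "none", "other")

#: CSV schema, in column order.  Booleans are stored as 0/1, missing as "".
SCHEMA_COLUMNS = (
    "id", "source", "age_years", "sex", "ethnicity", "histology_grade",
    "tumor_size_mm", "pt_category", "m_category", "lns_examined",
    "mln_count", "surgery", "followup_months", "event",
    "primary_site_stomach", "adenocarcinoma", "multiple_primaries",
    "remnant_gastric",
)

_INT_COLUMNS = ("age_years", "lns_examined", "mln_count", "event")
_FLOAT_COLUMNS = ("tumor_size_mm", "followup_months")
_BOOL_COLUMNS = ("primary_site_stomach", "adenocarcinoma",
                 "multiple_primaries", "remnant_gastric")
_ENUM_COLUMNS = {
    "source": SOURCES,
    "sex": SEXES,
    "ethnicity": ETHNICITIES,
    "histology_grade": GRADES,
    "pt_category": PT_CATEGORIES,
    "m_category": M_CATEGORIES,
    "surgery": SURGERIES,
}
#: every analytic field except id/source must be present for eligibility
_ANALYTIC_COLUMNS = tuple(c for c in SCHEMA_COLUMNS if c not in ("id", "source"))


class SchemaError(ValueError):
    """The CSV header does not match the documented cohort schema."""


class RowParseError(ValueError):
    """A required field in one data row could not be parsed."""


@dataclass
class PatientRecord:
    """One subject: covariates, pT, MLN count, follow-up time, event flag.

    ``None`` marks a missing optional value; eligibility screening
    excludes records with missing analytic fields rather than raising.
    """

    id: str
    source: str
    age_years: Optional[int] = None
    sex: Optional[str] = None
    ethnicity: Optional[str] = None
    histology_grade: Optional[str] = None
    tumor_size_mm: Optional[float] = None
    pt_category: Optional[str] = None
    m_category: Optional[str] = None
    lns_examined: Optional[int] = None
    mln_count: Optional[int] = None
    surgery: Optional[str] = None
    followup_months: Optional[float] = None
    event: Optional[int] = None
    primary_site_stomach: Optional[bool] = None
    adenocarcinoma: Optional[bool] = None
    multiple_primaries: Optional[bool] = None
    remnant_gastric: Optional[bool] = None

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("record id must be a non-empty string")
        for col, allowed in _ENUM_COLUMNS.items():
            v = getattr(self, col)
            if v is not None and v not in allowed:
                raise ValueError(f"{col}={v!r} not in {allowed}")
        for col in ("age_years", "lns_examined", "mln_count"):
            v = getattr(self, col)
            if v is not None and v < 0:
                raise ValueError(f"{col} must be >= 0, got {v}")
        if self.tumor_size_mm is not None and not self.tumor_size_mm > 0:
            raise ValueError("tumor_size_mm must be positive")
        if self.followup_months is not None and self.followup_months < 0:
            raise ValueError("followup_months must be >= 0")
        if self.event is not None and self.event not in (0, 1):
            raise ValueError("event must be 0 (censored) or 1 (death)")
        if (self.mln_count is not None and self.lns_examined is not None
                and self.mln_count > self.lns_examined):
            raise ValueError(
                f"mln_count ({self.mln_count}) exceeds lns_examined "
                f"({self.lns_examined})")


def _normalize_frame(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in SCHEMA_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")
    out = df.copy()
    for col in _INT_COLUMNS:
        out[col] = pd.array(out[col], dtype="Int64")
    for col in _FLOAT_COLUMNS:
        out[col] = pd.to_numeric(out[col]).astype("float64")
    for col in _BOOL_COLUMNS:
        out[col] = pd.array(out[col], dtype="boolean")
    for col in _ENUM_COLUMNS:
        vals = out[col]
        bad = vals.dropna()[~vals.dropna().isin(_ENUM_COLUMNS[col])]
        if len(bad):
            raise ValueError(
                f"column {col!r}: invalid value(s) {sorted(set(bad))!r}")
    # keep schema columns first, preserve any extra (e.g. stage) columns
    extra = [c for c in out.columns if c not in SCHEMA_COLUMNS]
    out = out[list(SCHEMA_COLUMNS) + extra]
    return out.reset_index(drop=True)


@dataclass
class Cohort:
    """An ordered collection of patient records backed by a DataFrame."""

    df: pd.DataFrame
    provenance: str = ""
    attrs: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.df = _normalize_frame(self.df)
        ids = self.df["id"]
        if ids.isna().any() or (ids == "").any():
            raise ValueError("every record needs a non-empty id")
        if ids.duplicated().any():
            dup = ids[ids.duplicated()].iloc[0]
            raise ValueError(f"duplicate record id {dup!r}")
        self._check_invariants()

    def _check_invariants(self) -> None:
        df = self.df
        both = df["mln_count"].notna() & df["lns_examined"].notna()
        if (df.loc[both, "mln_count"] > df.loc[both, "lns_examined"]).any():
            raise ValueError("mln_count exceeds lns_examined in some record")
        if (df["followup_months"].dropna() < 0).any():
            raise ValueError("negative followup_months")
        ev = df["event"].dropna()
        if (~ev.isin([0, 1])).any():
            raise ValueError("event must be 0 or 1")

    @classmethod
    def from_records(cls, records: Sequence[PatientRecord],
                     provenance: str = "") -> "Cohort":
        rows = [dataclasses.asdict(r) for r in records]
        df = pd.DataFrame(rows, columns=list(SCHEMA_COLUMNS))
        return cls(df, provenance=provenance)

    @property
    def records(self) -> list[PatientRecord]:
        out = []
        for row in self.df[list(SCHEMA_COLUMNS)].itertuples(index=False):
            kw = {}
            for col, v in zip(SCHEMA_COLUMNS, row):
                if pd.isna(v):
                    kw[col] = None
                elif col in _INT_COLUMNS:
                    kw[col] = int(v)
                elif col in _BOOL_COLUMNS:
                    kw[col] = bool(v)
                elif col in _FLOAT_COLUMNS:
                    kw[col] = float(v)
                else:
                    kw[col] = str(v)
            out.append(PatientRecord(**kw))
        return out

    def __len__(self) -> int:
        return len(self.df)


def read_cohort(path) -> Cohort:
    """Read a cohort CSV (see :data:`SCHEMA_COLUMNS`).

    Missing optional values are empty strings in the file and become NA;
    malformed values in typed columns raise :class:`RowParseError` naming
    the row; a missing column raises :class:`SchemaError` naming it.
    """
    path = Path(path)
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in SCHEMA_COLUMNS if c not in raw.columns]
    if missing:
        raise SchemaError(
            f"{path.name}: missing required column(s): {', '.join(missing)}")

    def parse_typed(col: str, kind: str) -> pd.Series:
        s = raw[col].str.strip()
        blank = s == ""
        num = pd.to_numeric(s.where(~blank), errors="coerce")
        bad = num.isna() & ~blank
        if kind in ("int", "bool"):
            nonint = num.notna() & (num % 1 != 0)
            bad |= nonint
        if kind == "bool":
            bad |= num.notna() & ~num.isin([0, 1])
        if bad.any():
            i = int(np.flatnonzero(bad.to_numpy())[0])
            raise RowParseError(
                f"{path.name}: row {i}: column {col!r}: cannot parse "
                f"{s.iloc[i]!r}")
        return num

    data = {"id": raw["id"], "source": raw["source"].replace("", pd.NA)}
    for col in _INT_COLUMNS:
        data[col] = parse_typed(col, "int")
    for col in _FLOAT_COLUMNS:
        data[col] = parse_typed(col, "float")
    for col in _BOOL_COLUMNS:
        data[col] = parse_typed(col, "bool")
    for col in _ENUM_COLUMNS:
        if col == "source":
            continue
        data[col] = raw[col].str.strip().replace("", pd.NA)
    df = pd.DataFrame(data)
    return Cohort(df, provenance=str(path))


def write_cohort(cohort: Cohort, path, extra_columns: Sequence[str] = ()) -> None:
    """Write a cohort CSV; booleans as 0/1, missing as empty string."""
    df = cohort.df[list(SCHEMA_COLUMNS) + list(extra_columns)].copy()
    for col in _BOOL_COLUMNS:
        df[col] = df[col].astype("Int64")
    df.to_csv(path, index=False, na_rep="")


# ---------------------------------------------------------------------------
# Eligibility screening
# ---------------------------------------------------------------------------

def _screen_failures(df: pd.DataFrame) -> list[tuple[str, pd.Series]]:
    """Ordered (criterion, fails) pairs; a missing value never fails a
    content criterion (it is charged to ``incomplete_data`` at the end)."""
    def nafalse(s):
        return s.fillna(False).astype(bool)

    return [
        ("non_gastric_primary", nafalse(df["primary_site_stomach"] == False)),  # noqa: E712
        ("age_under_18", nafalse(df["age_years"] < 18)),
        ("not_adenocarcinoma", nafalse(df["adenocarcinoma"] == False)),  # noqa: E712
        ("no_gastrectomy", df["surgery"].notna()
         & ~df["surgery"].isin(["partial_gastrectomy", "total_gastrectomy"])),
        ("lns_examined_le_15", nafalse(df["lns_examined"] <= 15)),
        ("fewer_than_7_mln", nafalse(df["mln_count"] < 7)),
        ("pt_not_t1_t4b", df["pt_category"].notna()
         & ~df["pt_category"].isin(["T1", "T2", "T3", "T4a", "T4b"])),
        ("not_m0", df["m_category"].notna() & (df["m_category"] != "M0")),
        ("survival_lt_1_month", nafalse(df["followup_months"] < 1)),
        ("multiple_primaries", nafalse(df["multiple_primaries"] == True)),  # noqa: E712
        ("remnant_gastric", nafalse(df["remnant_gastric"] == True)),  # noqa: E712
        ("incomplete_data", df[list(_ANALYTIC_COLUMNS)].isna().any(axis=1)),
    ]


@dataclass
class ScreeningReport:
    """Exclusion tally; each excluded record is charged to the FIRST
    failing criterion in the fixed order of :func:`screening_criteria`."""

    n_input: int
    n_eligible: int
    exclusions: dict[str, int]

    def __post_init__(self) -> None:
        if self.n_input != self.n_eligible + sum(self.exclusions.values()):
            raise ValueError("screening report does not reconcile")

    def to_frame(self) -> pd.DataFrame:
        rows = [{"criterion": k, "n_excluded": v}
                for k, v in self.exclusions.items()]
        rows.append({"criterion": "TOTAL_EXCLUDED",
                     "n_excluded": sum(self.exclusions.values())})
        rows.append({"criterion": "ELIGIBLE", "n_excluded": self.n_eligible})
        return pd.DataFrame(rows)


def screening_criteria() -> tuple[str, ...]:
    """The fixed exclusion-attribution order."""
    empty = pd.DataFrame({c: pd.Series(dtype="object")
                          for c in SCHEMA_COLUMNS})
    return tuple(name for name, _ in _screen_failures(_normalize_frame(empty)))


def screen_cohort(cohort: Cohort) -> tuple[Cohort, ScreeningReport]:
    """Apply the eligibility criteria; never raises on content.

    Retains records that are gastric primaries, adults, adenocarcinoma,
    resected (partial/total gastrectomy), with > 15 nodes examined,
    >= 7 metastatic nodes (pN3), pT1-T4b, M0, >= 1 month of follow-up,
    no multiple primaries, not remnant cancer, and no missing analytic
    field.  Exclusions are charged to the first failing criterion.
    """
    df = cohort.df
    n = len(df)
    assigned = np.full(n, -1)
    names = []
    for i, (name, fails) in enumerate(_screen_failures(df)):
        names.append(name)
        f = fails.to_numpy()
        newly = (assigned == -1) & f
        assigned[newly] = i
    eligible = assigned == -1
    counts = {name: int((assigned == i).sum()) for i, name in enumerate(names)}
    report = ScreeningReport(n_input=n, n_eligible=int(eligible.sum()),
                             exclusions=counts)
    kept = Cohort(df.loc[eligible].reset_index(drop=True),
                  provenance=f"{cohort.provenance} [screened]".strip(),
                  attrs=dict(cohort.attrs))
    return kept, report


# ---------------------------------------------------------------------------
# Table-1-style summaries
# ---------------------------------------------------------------------------

def round_half_up(x: float, decimals: int = 1) -> float:
    """Decimal half-up rounding (presentation convention for percentages)."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


_CATEGORICAL_VARS = ("sex", "ethnicity", "histology_grade", "pt_category",
                     "surgery")
#: derived/staging columns are summarized too when present on the frame
_OPTIONAL_CATEGORICAL = ("n_eighth", "n_modified",
                         "stage_eighth", "stage_modified")
_CONTINUOUS_VARS = (
    ("age_years", "mean_sd"),
    ("tumor_size_mm", "median_range"),
    ("lns_examined", "median_range"),
    ("mln_count", "median_range"),
)


@dataclass
class CohortSummary:
    categorical: pd.DataFrame
    continuous: pd.DataFrame
    strata: tuple[str, ...]

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("# categorical variables: n (percent of stratum)\n")
            self.categorical.to_csv(fh, sep="\t", index=False)
            fh.write("\n# continuous variables\n")
            self.continuous.to_csv(fh, sep="\t", index=False)


def _levels_in_order(var: str, observed) -> list[str]:
    catalog = dict(_ENUM_COLUMNS).get(var)
    observed = list(dict.fromkeys(observed))
    if catalog is None:
        return sorted(observed)
    ordered = [l for l in catalog if l in observed]
    return ordered + [l for l in observed if l not in catalog]


def summarize(cohort: Cohort, by_source: bool = False) -> CohortSummary:
    """Demographics table: per-level counts/percentages, mean +/- SD age,
    median (range) node counts and tumor size; with ``by_source``,
    two-sided chi-square per categorical level and Mann-Whitney U for
    continuous variables between the two sources."""
    df = cohort.df
    if len(df) == 0:
        raise ValueError("cannot summarize an empty cohort")
    if by_source:
        observed_sources = [s for s in SOURCES if (df["source"] == s).any()]
        observed_sources += [s for s in df["source"].dropna().unique()
                             if s not in observed_sources]
        if len(observed_sources) < 2:
            raise ValueError("by_source summary needs >= 2 sources")
        strata = {s: df[df["source"] == s] for s in observed_sources}
    else:
        strata = {}
    for name, sub in strata.items():
        if len(sub) == 0:
            raise ValueError(f"stratum {name!r} has zero records")

    cat_vars = list(_CATEGORICAL_VARS) + [c for c in _OPTIONAL_CATEGORICAL
                                          if c in df.columns]
    cat_rows = []
    for var in cat_vars:
        col = df[var].dropna()
        levels = _levels_in_order(var, col.unique())
        denom_all = len(col)
        for lv in levels:
            row = {"variable": var, "level": lv}
            n_all = int((col == lv).sum())
            row["n_overall"] = n_all
            row["pct_overall"] = round_half_up(100.0 * n_all / denom_all)
            for sname, sub in strata.items():
                scol = sub[var].dropna()
                n_s = int((scol == lv).sum())
                row[f"n_{sname}"] = n_s
                row[f"pct_{sname}"] = (round_half_up(100.0 * n_s / len(scol))
                                       if len(scol) else float("nan"))
            if strata:
                table = np.array(
                    [[(strata[s][var].dropna() == lv).sum(),
                      (strata[s][var].dropna() != lv).sum()]
                     for s in strata], dtype=float).T
                if (table.sum(axis=0) > 0).all() and (table.sum(axis=1) > 0).all():
                    chi2, p, _, _ = _stats.chi2_contingency(
                        table, correction=False)
                    row["chi2"] = float(chi2)
                    row["p_value"] = float(p)
                else:
                    row["chi2"] = float("nan")
                    row["p_value"] = float("nan")
            cat_rows.append(row)

    cont_rows = []
    for var, kind in _CONTINUOUS_VARS:
        col = df[var].dropna().astype(float)
        if kind == "mean_sd":
            stats_ = {"mean": float(col.mean()),
                      "sd": float(col.std(ddof=1)) if len(col) > 1 else 0.0}
        else:
            stats_ = {"median": float(col.median()),
                      "min": float(col.min()), "max": float(col.max())}
        p_value = float("nan")
        if len(strata) == 2:
            a, b = [s[var].dropna().astype(float) for s in strata.values()]
            if len(a) and len(b):
                _, p_value = _stats.mannwhitneyu(a, b,
                                                 alternative="two-sided")
        for stat, val in stats_.items():
            row = {"variable": var, "statistic": stat, "overall": val}
            for sname, sub in strata.items():
                scol = sub[var].dropna().astype(float)
                if not len(scol):
                    row[sname] = float("nan")
                elif stat == "mean":
                    row[sname] = float(scol.mean())
                elif stat == "sd":
                    row[sname] = (float(scol.std(ddof=1))
                                  if len(scol) > 1 else 0.0)
                elif stat == "median":
                    row[sname] = float(scol.median())
                elif stat == "min":
                    row[sname] = float(scol.min())
                else:
                    row[sname] = float(scol.max())
            row["p_value"] = float(p_value)
            cont_rows.append(row)

    return CohortSummary(categorical=pd.DataFrame(cat_rows),
                         continuous=pd.DataFrame(cont_rows),
                         strata=tuple(strata))
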