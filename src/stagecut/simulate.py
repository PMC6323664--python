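"""Synthetic N3 gastric-cancer cohorts with a plantable true MLN cutoff.

The generator emulates the statistical structure the downstream analysis
assumes: metastatic-node counts from a truncated negative binomial
(median near 14, support 7-90), more nodes examined than positive
(floored at 16), a Table-1-like covariate mix, and survival times whose
hazard is proportional with a step when the MLN count exceeds a
configurable true cutoff, administratively censored at five years.

All randomness flows from one seed through a single Generator in a
fixed, documented draw order (MLN counts, examined-node offsets, sex,
ethnicity, age, grade, tumor size, pT, surgery, event times, random
censoring, ineligible-record planting); no per-record seeds.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from math import log
import numpy as np
import pandas as pd
import yaml

from .cohort import Cohort, SCHEMA_COLUMNS

__all__ = ["SimulationConfig", "generate", "default_paperlike_config"]


def _paperlike_mix() -> dict:
    """Covariate margins matching the pooled SEER + FMUUH demographics."""
    return {
        "male_p": 0.617,
        "ethnicity_p": {"white": 0.240, "asian": 0.536, "black": 0.091,
                        "hispanic": 0.126, "native_american": 0.007},
        "grade_g3_g4_p": 0.838,
        "pt_p": {"T1": 0.021, "T2": 0.042, "T3": 0.266,
                 "T4a": 0.501, "T4b": 0.170},
        "age_mean": 62.4,
        "age_sd": 13.4,
        "tumor_size_log_mean": log(60.0),
        "tumor_size_log_sd": 0.55,
        "total_gastrectomy_p": 0.41,
    }


def _paperlike_effects() -> dict:
    """Log hazard ratios in the neighborhood of the multivariate fits on
    the pooled registry data."""
    return {
        "age_ge_65": log(1.47),
        "ethnicity_asian": log(0.66),
        "ethnicity_hispanic": log(0.85),
        "pt_T2": log(1.18),
        "pt_T3": log(1.66),
        "pt_T4a": log(1.86),
        "pt_T4b": log(2.18),
    }


#: covariate keys accepted in ``covariate_effects``
EFFECT_KEYS = (
    "age_ge_65", "female", "grade_g3_g4", "tumor_size_gt_60",
    "total_gastrectomy",
    "ethnicity_asian", "ethnicity_black", "ethnicity_hispanic",
    "ethnicity_native_american", "ethnicity_other",
    "pt_T2", "pt_T3", "pt_T4a", "pt_T4b",
)


@dataclass
class SimulationConfig:
    """All knobs of the generator; defaults are the paper-like study
    conditions (n = 2753, step at 13 MLNs with log HR ln 1.6, exponential
    baseline, five-year administrative censoring)."""

    n: int = 2753
    seed: int = 0
    # negative binomial (mean, dispersion k; variance = m + m^2/k),
    # truncated by rejection to [mln_min, mln_max]
    mln_mean: float = 12.0
    mln_dispersion: float = 1.6
    mln_min: int = 7
    mln_max: int = 90
    # examined nodes = positive nodes + Poisson offset, floored at 16
    lns_offset_mean: float = 12.0
    lns_floor: int = 16
    true_cutoff: int = 13
    log_hr_step: float = log(1.6)
    linear_mln_log_hr: float = 0.0     # optional secondary linear term
    covariate_effects: dict = field(default_factory=dict)
    baseline_hazard: float = 0.012     # events per month at the reference
    weibull_shape: float = 1.0         # 1.0 = exponential baseline
    admin_censor_months: float = 60.0
    random_censor_rate: float = 0.0
    covariate_mix: dict = field(default_factory=_paperlike_mix)
    ineligible_fraction: float = 0.0

    def validate(self) -> None:
        if self.n <= 0:
            raise ValueError("n must be positive")
        if not (0 <= self.mln_min <= self.mln_max):
            raise ValueError("invalid MLN truncation bounds")
        if self.mln_mean <= 0 or self.mln_dispersion <= 0:
            raise ValueError("negative-binomial parameters must be positive")
        if self.lns_offset_mean < 0:
            raise ValueError("lns_offset_mean must be >= 0")
        if not (8 <= self.true_cutoff <= 20):
            raise ValueError("true_cutoff must lie in [8, 20]")
        if self.baseline_hazard <= 0 or self.weibull_shape <= 0:
            raise ValueError("baseline hazard and shape must be positive")
        if self.admin_censor_months <= 0:
            raise ValueError("admin_censor_months must be positive")
        if self.random_censor_rate < 0:
            raise ValueError("random_censor_rate must be >= 0")
        if not (0 <= self.ineligible_fraction < 1):
            raise ValueError("ineligible_fraction must lie in [0, 1)")
        unknown = set(self.covariate_effects) - set(EFFECT_KEYS)
        if unknown:
            raise ValueError(f"unknown covariate_effects key(s): "
                             f"{sorted(unknown)}")
        mix = self.covariate_mix
        for key in ("male_p", "grade_g3_g4_p", "total_gastrectomy_p"):
            if not (0 <= mix[key] <= 1):
                raise ValueError(f"covariate_mix[{key!r}] outside [0, 1]")
        for key in ("ethnicity_p", "pt_p"):
            probs = np.array(list(mix[key].values()), float)
            if (probs < 0).any() or probs.sum() <= 0:
                raise ValueError(f"covariate_mix[{key!r}] invalid")
        if mix["age_sd"] <= 0 or mix["tumor_size_log_sd"] <= 0:
            raise ValueError("age_sd and tumor_size_log_sd must be positive")

    # -- YAML round-trip ---------------------------------------------------
    def to_yaml(self, path=None) -> str:
        text = yaml.safe_dump(dataclasses.asdict(self), sort_keys=False)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_yaml(cls, source) -> "SimulationConfig":
        if hasattr(source, "read"):
            data = yaml.safe_load(source.read())
        else:
            text = str(source)
            if "\n" not in text and text.endswith((".yaml", ".yml")):
                with open(text) as fh:
                    data = yaml.safe_load(fh)
            else:
                data = yaml.safe_load(text)
        cfg = cls(**data)
        cfg.validate()
        return cfg


def default_paperlike_config(n: int = 2753, seed: int = 0) -> SimulationConfig:
    """Study-condition defaults: Table-1-like margins with the planted
    step at 13 MLNs and paper-magnitude covariate effects."""
    return SimulationConfig(n=n, seed=seed,
                            covariate_effects=_paperlike_effects())


def _truncated_negbin(rng: np.random.Generator, n: int, mean: float,
                      dispersion: float, lo: int, hi: int) -> np.ndarray:
    """Rejection-sample NB(mean, dispersion) into [lo, hi]."""
    k = dispersion
    p = k / (k + mean)
    out = np.empty(n, dtype=int)
    need = np.arange(n)
    guard = 0
    while need.size:
        draw = rng.negative_binomial(k, p, size=need.size)
        ok = (draw >= lo) & (draw <= hi)
        out[need[ok]] = draw[ok]
        need = need[~ok]
        guard += 1
        if guard > 1000:
            raise RuntimeError("MLN truncation rejection did not terminate")
    return out


_INELIGIBLE_CRITERIA = (
    "non_gastric_primary", "age_under_18", "not_adenocarcinoma",
    "no_gastrectomy", "lns_examined_le_15", "fewer_than_7_mln",
    "pt_not_t1_t4b", "not_m0", "survival_lt_1_month",
    "multiple_primaries", "remnant_gastric", "incomplete_data",
)


def generate(config: SimulationConfig) -> Cohort:
    """Draw one cohort; identical configs give identical cohorts.

    Survival time is min(event time, random censor time, administrative
    censor), floored at one month (the cohorts this emulates exclude
    peri-operative deaths, so eligible records always clear the one-month
    screening criterion).  With ``ineligible_fraction`` > 0 that share of
    records is mutated post hoc to violate exactly one screening
    criterion each; their ids are listed in
    ``cohort.attrs["planted_ineligible"]``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n
    mix = config.covariate_mix

    # (1) MLN counts, (2) examined-node offsets
    mln = _truncated_negbin(rng, n, config.mln_mean, config.mln_dispersion,
                            config.mln_min, config.mln_max)
    offset = rng.poisson(config.lns_offset_mean, size=n)
    lns = np.maximum(mln + offset, config.lns_floor)

    # (3)-(9) covariates, in fixed order
    sex = np.where(rng.random(n) < mix["male_p"], "male", "female")
    eth_levels = list(mix["ethnicity_p"])
    eth_p = np.array([mix["ethnicity_p"][k] for k in eth_levels], float)
    eth_p = eth_p / eth_p.sum()
    ethnicity = rng.choice(eth_levels, size=n, p=eth_p)
    age = np.clip(np.rint(rng.normal(mix["age_mean"], mix["age_sd"], n)),
                  18, 100).astype(int)
    grade = np.where(rng.random(n) < mix["grade_g3_g4_p"], "G3_G4", "G1_G2")
    size = np.clip(np.rint(np.exp(rng.normal(mix["tumor_size_log_mean"],
                                             mix["tumor_size_log_sd"], n))),
                   2, 220).astype(float)
    pt_levels = list(mix["pt_p"])
    pt_p = np.array([mix["pt_p"][k] for k in pt_levels], float)
    pt_p = pt_p / pt_p.sum()
    pt = rng.choice(pt_levels, size=n, p=pt_p)
    surgery = np.where(rng.random(n) < mix["total_gastrectomy_p"],
                       "total_gastrectomy", "partial_gastrectomy")

    # linear predictor
    eta = np.zeros(n)
    indicators = {
        "age_ge_65": age >= 65,
        "female": sex == "female",
        "grade_g3_g4": grade == "G3_G4",
        "tumor_size_gt_60": size > 60,
        "total_gastrectomy": surgery == "total_gastrectomy",
    }
    for lv in ("asian", "black", "hispanic", "native_american", "other"):
        indicators[f"ethnicity_{lv}"] = ethnicity == lv
    for lv in ("T2", "T3", "T4a", "T4b"):
        indicators[f"pt_{lv}"] = pt == lv
    for key, loghr in config.covariate_effects.items():
        eta += loghr * indicators[key]
    eta += config.log_hr_step * (mln > config.true_cutoff)
    eta += config.linear_mln_log_hr * (mln - config.mln_min)

    # (10) event times: H(t) = baseline * exp(eta) * t^shape
    exp1 = rng.exponential(1.0, size=n)
    scale = exp1 / (config.baseline_hazard * np.exp(eta))
    t_event = scale ** (1.0 / config.weibull_shape)

    # (11) censoring
    if config.random_censor_rate > 0:
        t_cens = rng.exponential(1.0 / config.random_censor_rate, size=n)
    else:
        t_cens = np.full(n, np.inf)
    t_admin = config.admin_censor_months
    followup = np.minimum.reduce([t_event, t_cens,
                                  np.full(n, t_admin)])
    event = (t_event <= np.minimum(t_cens, t_admin)).astype(int)
    followup = np.maximum(followup, 1.0)

    df = pd.DataFrame({
        "id": [f"SY{i:06d}" for i in range(n)],
        "source": "SYNTH",
        "age_years": age,
        "sex": sex,
        "ethnicity": ethnicity,
        "histology_grade": grade,
        "tumor_size_mm": size,
        "pt_category": pt,
        "m_category": "M0",
        "lns_examined": lns,
        "mln_count": mln,
        "surgery": surgery,
        "followup_months": followup,
        "event": event,
        "primary_site_stomach": True,
        "adenocarcinoma": True,
        "multiple_primaries": False,
        "remnant_gastric": False,
    }, columns=list(SCHEMA_COLUMNS))

    # (12) plant ineligible records
    planted: dict[str, str] = {}
    m = int(round(config.ineligible_fraction * n))
    if m:
        rows = rng.choice(n, size=m, replace=False)
        crits = rng.integers(len(_INELIGIBLE_CRITERIA), size=m)
        for row, ci in zip(rows, crits):
            crit = _INELIGIBLE_CRITERIA[ci]
            if crit == "non_gastric_primary":
                df.loc[row, "primary_site_stomach"] = False
            elif crit == "age_under_18":
                df.loc[row, "age_years"] = int(rng.integers(10, 18))
            elif crit == "not_adenocarcinoma":
                df.loc[row, "adenocarcinoma"] = False
            elif crit == "no_gastrectomy":
                df.loc[row, "surgery"] = "none"
            elif crit == "lns_examined_le_15":
                df.loc[row, "lns_examined"] = 15
                df.loc[row, "mln_count"] = min(int(df.loc[row, "mln_count"]),
                                               15)
            elif crit == "fewer_than_7_mln":
                df.loc[row, "mln_count"] = int(rng.integers(1, 7))
            elif crit == "pt_not_t1_t4b":
                df.loc[row, "pt_category"] = "other"
            elif crit == "not_m0":
                df.loc[row, "m_category"] = "M1"
            elif crit == "survival_lt_1_month":
                df.loc[row, "followup_months"] = 0.5
                df.loc[row, "event"] = 1
            elif crit == "multiple_primaries":
                df.loc[row, "multiple_primaries"] = True
            elif crit == "remnant_gastric":
                df.loc[row, "remnant_gastric"] = True
            else:  # incomplete_data
                df.loc[row, "tumor_size_mm"] = np.nan
            planted[str(df.loc[row, "id"])] = crit

    return Cohort(df, provenance=f"synthetic(seed={config.seed}, n={n})",
                  attrs={"planted_ineligible": planted,
                         "true_cutoff": config.true_cutoff})
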