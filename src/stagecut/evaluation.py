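"""Staging-system performance: homogeneity, discrimination, parsimony.

For a staged cohort the three Table-4-style metrics are

* likelihood-ratio chi-square (homogeneity): 2 * (log partial likelihood
  of a Cox model with stage as a categorical factor minus the null log
  partial likelihood), df = number of non-empty stages - 1;
* linear-trend chi-square (discriminatory ability / gradient
  monotonicity): the same likelihood-ratio construction with stage
  entered as a single consecutive-integer score, df = 1 (a score-test
  variant is available behind ``trend_method="score"``);
* AIC of the categorical model: -2 * logPL + 2 * n_params; smaller is
  better.

Because the trend (score) model is nested in the categorical model,
trend chi-square can never exceed the likelihood-ratio chi-square.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence, Union

import numpy as np
import pandas as pd
from scipy.stats import chi2 as _chi2_dist

from .cohort import Cohort
from .cox import fit_cox_arrays, _loglik_grad_hess, _cox_structures
from .staging import STAGE_ORDER, RestagedCohort

__all__ = ["SystemEvaluation", "SystemComparison", "evaluate_system",
           "compare_systems"]


@dataclass
class SystemEvaluation:
    system_name: str
    lr_chi2: float
    lr_df: int
    lr_p: float
    trend_chi2: float
    trend_p: float
    aic: float
    n_subjects: int
    n_events: int
    trend_method: str = "lr"

    def to_row(self) -> dict:
        return {
            "system": self.system_name,
            "trend_chi2": self.trend_chi2, "trend_p": self.trend_p,
            "lr_chi2": self.lr_chi2, "lr_df": self.lr_df, "lr_p": self.lr_p,
            "aic": self.aic,
            "n_subjects": self.n_subjects, "n_events": self.n_events,
        }


def _staged_inputs(staged, stage_col):
    if isinstance(staged, RestagedCohort):
        df = staged.cohort.df
        name = staged.system.name
    elif isinstance(staged, Cohort):
        df = staged.df
        name = None
    else:
        df = staged
        name = None
    if stage_col not in df.columns:
        raise ValueError(f"no {stage_col!r} column; restage the cohort first")
    if df[stage_col].isna().any():
        raise ValueError("every record must carry a stage label")
    return df, name


def evaluate_system(staged: Union[RestagedCohort, Cohort, pd.DataFrame],
                    stage_order: Sequence[str] = STAGE_ORDER,
                    stage_col: str = "stage",
                    name: str = None,
                    ties: str = "breslow",
                    trend_method: str = "lr") -> SystemEvaluation:
    """Evaluate one staging system on a staged cohort."""
    df, inferred = _staged_inputs(staged, stage_col)
    name = name or inferred or "system"
    stages = df[stage_col]
    unknown = set(stages.unique()) - set(stage_order)
    if unknown:
        raise ValueError(f"stage label(s) {sorted(unknown)} outside the "
                         f"declared order {tuple(stage_order)}")
    present = [s for s in stage_order if (stages == s).any()]
    if len(present) < 2:
        raise ValueError("evaluation needs >= 2 non-empty stages")

    t = df["followup_months"].to_numpy(float)
    e = df["event"].to_numpy(float)

    # categorical model (reference = lowest non-empty stage)
    Xcat = np.column_stack([(stages == s).to_numpy(float)
                            for s in present[1:]])
    cat_names = [f"stage={s}" for s in present[1:]]
    cat_fit = fit_cox_arrays(t, e, Xcat, cat_names, ties=ties)
    ll0 = cat_fit.null_log_likelihood
    lr_chi2 = max(2.0 * (cat_fit.log_partial_likelihood - ll0), 0.0)
    lr_df = len(present) - 1
    lr_p = float(_chi2_dist.sf(lr_chi2, lr_df))
    aic = -2.0 * cat_fit.log_partial_likelihood + 2.0 * cat_fit.n_params

    # trend model: consecutive integer scores in the declared order
    score_of = {s: i + 1.0 for i, s in enumerate(present)}
    score = stages.map(score_of).to_numpy(float)[:, None]
    if trend_method == "lr":
        trend_fit = fit_cox_arrays(t, e, score, ["stage_score"], ties=ties)
        trend_chi2 = max(
            2.0 * (trend_fit.log_partial_likelihood - ll0), 0.0)
    elif trend_method == "score":
        struct = _cox_structures(t, e.astype(int), score, ties)
        _, _, Xs, ev_idx, gid, gs, d_g, m_g, f = struct
        _, grad, hess = _loglik_grad_hess(np.zeros(1), Xs, ev_idx, gid,
                                          gs, d_g, m_g, f)
        trend_chi2 = float(grad @ np.linalg.solve(-hess, grad))
    else:
        raise ValueError("trend_method must be 'lr' or 'score'")
    trend_p = float(_chi2_dist.sf(trend_chi2, 1))

    return SystemEvaluation(system_name=name, lr_chi2=lr_chi2, lr_df=lr_df,
                            lr_p=lr_p, trend_chi2=trend_chi2,
                            trend_p=trend_p, aic=aic,
                            n_subjects=cat_fit.n_subjects,
                            n_events=cat_fit.n_events,
                            trend_method=trend_method)


_METRICS = ("lr_chi2", "trend_chi2", "aic")


@dataclass
class SystemComparison:
    """Per-metric verdicts; higher LR/trend chi-square is better, lower
    AIC is better."""

    first: SystemEvaluation
    second: SystemEvaluation
    margins: dict[str, float]      # second minus first, per metric
    winners: dict[str, str]        # metric -> system name or "tie"
    overall: str                   # system name if it wins all metrics

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for metric in _METRICS:
            rows.append({
                "metric": metric,
                self.first.system_name: getattr(self.first, metric),
                self.second.system_name: getattr(self.second, metric),
                "margin": self.margins[metric],
                "better": self.winners[metric],
            })
        return pd.DataFrame(rows)


def compare_systems(first: SystemEvaluation,
                    second: SystemEvaluation) -> SystemComparison:
    """Compare two evaluations computed on the same cohort."""
    if (first.n_subjects, first.n_events) != (second.n_subjects,
                                              second.n_events):
        raise ValueError(
            "evaluations come from different cohorts: "
            f"{first.n_subjects}/{first.n_events} vs "
            f"{second.n_subjects}/{second.n_events} subjects/events")
    margins, winners = {}, {}
    for metric in _METRICS:
        a, b = getattr(first, metric), getattr(second, metric)
        margins[metric] = b - a
        if a == b:
            winners[metric] = "tie"
        elif metric == "aic":
            winners[metric] = (first.system_name if a < b
                               else second.system_name)
        else:
            winners[metric] = (first.system_name if a > b
                               else second.system_name)
    names = {first.system_name, second.system_name}
    overall = "tie"
    for nm in names:
        if all(winners[m] == nm for m in _METRICS):
            overall = nm
    return SystemComparison(first=first, second=second, margins=margins,
                            winners=winners, overall=overall)
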