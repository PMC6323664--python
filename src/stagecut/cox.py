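"""Cox proportional-hazards fitting and the two-step N3 validation.

The two-step procedure asks whether the modified N3 split (mN3a 7-13 vs
mN3b > 13 metastatic nodes) carries prognostic information beyond the
eighth-edition split (N3a 7-15 vs N3b > 15): step 1 fits the
univariate-significant factors together with the eighth-edition term
(mN3 excluded); step 2 adds the mN3 term and reads both N terms' Wald
p-values.  The two indicators disagree only on patients with 14-15
metastatic nodes, so they are deliberately collinear-but-distinct and
both enter step 2 as separate binary terms.

The partial likelihood is maximized by Newton-Raphson with analytic
gradient and Hessian; tied event times use Breslow's approximation by
default (Efron's correction behind a flag).  Wald confidence intervals
and p-values come from the inverse observed information.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy.stats import norm as _norm

from .cohort import Cohort
from .survival import km_fit, logrank, survival_at

__all__ = [
    "CoxFit", "UnivariateScreen", "TwoStepResult", "ConvergenceError",
    "fit_cox", "fit_cox_arrays", "univariate_screen", "two_step",
    "with_derived_factors", "design_matrix", "FACTOR_LEVELS",
]


class ConvergenceError(RuntimeError):
    """Newton-Raphson failed (non-convergence or suspected separation)."""


#: factor catalog; the FIRST level is the reference level
FACTOR_LEVELS = {
    "age_group": ("<65", ">=65"),
    "sex": ("male", "female"),
    "ethnicity": ("white", "asian", "black", "hispanic",
                  "native_american", "other"),
    "histology_grade": ("G1_G2", "G3_G4", "other"),
    "tumor_size_group": ("<=60", ">60"),
    "pt_category": ("T1", "T2", "T3", "T4a", "T4b"),
    "surgery": ("partial_gastrectomy", "total_gastrectomy"),
    "n_eighth": ("N3a", "N3b"),
    "n_modified": ("mN3a", "mN3b"),
}

_EIGHTH_CUTOFF = 15


def with_derived_factors(df: pd.DataFrame,
                         modified_cutoff: int = 13) -> pd.DataFrame:
    """Add on-demand dichotomies (age, tumor size) and both N3
    subclassifications to a cohort frame."""
    out = df.copy()
    age = out["age_years"].astype(float)
    out["age_group"] = np.where(age >= 65, ">=65", "<65")
    size = out["tumor_size_mm"].astype(float)
    out["tumor_size_group"] = np.where(size > 60, ">60", "<=60")
    mln = out["mln_count"].astype(float)
    if (mln < 7).any():
        raise ValueError("N3 subclassification requires mln_count >= 7")
    out["n_eighth"] = np.where(mln > _EIGHTH_CUTOFF, "N3b", "N3a")
    out["n_modified"] = np.where(mln > modified_cutoff, "mN3b", "mN3a")
    return out


def design_matrix(df: pd.DataFrame, terms: Sequence[str],
                  modified_cutoff: int = 13
                  ) -> tuple[np.ndarray, list[str]]:
    """Dummy-encode factors against their catalog reference levels.

    Only observed levels generate columns; the reference is the first
    catalog level present in the data.
    """
    need_derived = {"age_group", "tumor_size_group", "n_eighth", "n_modified"}
    if any(t in need_derived and t not in df.columns for t in terms):
        df = with_derived_factors(df, modified_cutoff)
    cols, names = [], []
    for term in terms:
        if term not in FACTOR_LEVELS:
            raise ValueError(f"unknown factor {term!r}")
        values = df[term]
        unknown = set(values.dropna().unique()) - set(FACTOR_LEVELS[term])
        if unknown:
            raise ValueError(f"factor {term!r}: unexpected level(s) "
                             f"{sorted(unknown)}")
        observed = [lv for lv in FACTOR_LEVELS[term]
                    if (values == lv).any()]
        if len(observed) < 2:
            raise ValueError(
                f"factor {term!r} has fewer than 2 observed levels")
        for lv in observed[1:]:
            names.append(f"{term}={lv}")
            cols.append((values == lv).to_numpy(dtype=float))
    X = np.column_stack(cols) if cols else np.empty((len(df), 0))
    return X, names


# ---------------------------------------------------------------------------
# Partial-likelihood Newton solver
# ---------------------------------------------------------------------------

def _cox_structures(time: np.ndarray, event: np.ndarray, X: np.ndarray,
                    ties: str):
    """Sort descending by time and precompute tie-group bookkeeping."""
    order = np.argsort(-time, kind="stable")
    t = time[order]
    e = event[order].astype(bool)
    Xs = np.ascontiguousarray(X[order])
    ev_idx = np.flatnonzero(e)
    ev_t = t[ev_idx]
    if ev_idx.size:
        new = np.r_[True, ev_t[1:] != ev_t[:-1]]
        gid = np.cumsum(new) - 1
        group_starts = np.flatnonzero(new)
        d_g = np.diff(np.r_[group_starts, ev_idx.size])
        # risk-set size for each tie group = #{time >= tau}
        taus = ev_t[group_starts]
        m_g = np.searchsorted(-t, -taus, side="right")
        l_within = np.arange(ev_idx.size) - np.repeat(group_starts, d_g)
        if ties == "efron":
            f = l_within / d_g[gid]
        elif ties == "breslow":
            f = np.zeros(ev_idx.size)
        else:
            raise ValueError("ties must be 'breslow' or 'efron'")
    else:
        gid = group_starts = d_g = m_g = f = np.empty(0, dtype=int)
        f = np.empty(0)
    return t, e, Xs, ev_idx, gid, group_starts, d_g, m_g, f


def _loglik_grad_hess(beta, Xs, ev_idx, gid, group_starts, d_g, m_g, f):
    n, p = Xs.shape
    eta = Xs @ beta if p else np.zeros(n)
    shift = eta.max() if n else 0.0
    w = np.exp(eta - shift)
    if ev_idx.size == 0:
        return 0.0, np.zeros(p), np.zeros((p, p))
    S0c = np.cumsum(w)
    S0_g = S0c[m_g - 1]
    w_ev = w[ev_idx]
    D0_g = np.add.reduceat(w_ev, group_starts)
    A0 = S0_g[gid] - f * D0_g[gid]
    ll = float(np.sum(eta[ev_idx] - shift) - np.sum(np.log(A0)))
    if p == 0:
        return ll, np.zeros(0), np.zeros((0, 0))

    Xw = Xs * w[:, None]
    S1c = np.cumsum(Xw, axis=0)
    S1_g = S1c[m_g - 1]
    X_ev = Xs[ev_idx]
    D1_g = np.add.reduceat(Xw[ev_idx], group_starts, axis=0)
    A1 = S1_g[gid] - f[:, None] * D1_g[gid]
    psi = A1 / A0[:, None]
    grad = X_ev.sum(axis=0) - psi.sum(axis=0)

    XXw = Xw[:, :, None] * Xs[:, None, :]
    S2c = np.cumsum(XXw, axis=0)
    S2_g = S2c[m_g - 1]
    D2_g = np.add.reduceat(XXw[ev_idx], group_starts, axis=0)
    A2 = S2_g[gid] - f[:, None, None] * D2_g[gid]
    hess = -(np.einsum("e,epq->pq", 1.0 / A0, A2)
             - np.einsum("ep,eq->pq", psi, psi))
    return ll, grad, hess


@dataclass
class CoxFit:
    """A fitted Cox model: per-term Wald inference plus the quantities
    the staging comparison needs (log partial likelihood, counts)."""

    terms: list[str]
    coefficients: np.ndarray
    se: np.ndarray
    hazard_ratios: np.ndarray
    ci95: np.ndarray              # (p, 2): low, high on the HR scale
    p_values: np.ndarray
    log_partial_likelihood: float
    null_log_likelihood: float
    n_params: int
    n_subjects: int
    n_events: int
    ties: str

    @property
    def lr_chi2(self) -> float:
        return 2.0 * (self.log_partial_likelihood - self.null_log_likelihood)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "term": self.terms,
            "coef": self.coefficients,
            "se": self.se,
            "hr": self.hazard_ratios,
            "hr_ci_low": self.ci95[:, 0],
            "hr_ci_high": self.ci95[:, 1],
            "p_value": self.p_values,
        })

    def term_row(self, prefix: str) -> Optional[dict]:
        """The (single) non-reference row of a binary factor, or None."""
        for i, name in enumerate(self.terms):
            if name.startswith(prefix + "="):
                return {"term": name,
                        "coef": float(self.coefficients[i]),
                        "hr": float(self.hazard_ratios[i]),
                        "ci_low": float(self.ci95[i, 0]),
                        "ci_high": float(self.ci95[i, 1]),
                        "p_value": float(self.p_values[i])}
        return None


def fit_cox_arrays(time, event, X, names: Sequence[str],
                   ties: str = "breslow", max_iter: int = 60,
                   tol: float = 1e-10) -> CoxFit:
    """Maximize the partial likelihood by Newton-Raphson.

    Raises :class:`ConvergenceError` on non-convergence or when
    coefficients diverge (complete separation).
    """
    time = np.asarray(time, float)
    event = np.asarray(event, float).astype(int)
    X = np.asarray(X, float)
    if X.ndim == 1:
        X = X[:, None]
    n, p = X.shape
    if len(names) != p:
        raise ValueError("names must match design-matrix columns")
    struct = _cox_structures(time, event, X, ties)
    _, _, Xs, ev_idx, gid, gs, d_g, m_g, f = struct

    beta = np.zeros(p)
    ll, grad, hess = _loglik_grad_hess(beta, Xs, ev_idx, gid, gs, d_g, m_g, f)
    ll0 = ll
    n_events = int(event.sum())
    if p == 0:
        return CoxFit(terms=[], coefficients=np.empty(0), se=np.empty(0),
                      hazard_ratios=np.empty(0), ci95=np.empty((0, 2)),
                      p_values=np.empty(0), log_partial_likelihood=ll,
                      null_log_likelihood=ll0, n_params=0, n_subjects=n,
                      n_events=n_events, ties=ties)

    converged = False
    for it in range(max_iter):
        try:
            delta = np.linalg.solve(-hess, grad)
        except np.linalg.LinAlgError as exc:
            raise ConvergenceError(
                f"singular information matrix at iteration {it} "
                "(collinear or separated design)") from exc
        step = 1.0
        while True:
            cand = beta + step * delta
            ll_new, grad_new, hess_new = _loglik_grad_hess(
                cand, Xs, ev_idx, gid, gs, d_g, m_g, f)
            if ll_new >= ll - 1e-12 or step < 1e-10:
                break
            step *= 0.5
        if step < 1e-10 and ll_new < ll:
            raise ConvergenceError(
                f"step-halving failed at iteration {it} (ll={ll:.6f})")
        improved = ll_new - ll
        beta, ll, grad, hess = cand, ll_new, grad_new, hess_new
        if np.abs(beta).max() > 40:
            raise ConvergenceError(
                "coefficients diverging (complete separation suspected); "
                f"max |beta| = {np.abs(beta).max():.1f} at iteration {it}")
        if abs(improved) < tol * (1.0 + abs(ll)) and \
                np.abs(grad).max() < 1e-6 * max(1, n_events):
            converged = True
            break
    if not converged:
        raise ConvergenceError(
            f"no convergence after {max_iter} iterations "
            f"(|grad|_max = {np.abs(grad).max():.3e})")
    if np.abs(beta).max() > 20:
        raise ConvergenceError(
            "coefficient magnitude exceeds 20 at convergence "
            "(complete separation suspected)")

    cov = np.linalg.inv(-hess)
    se = np.sqrt(np.clip(np.diag(cov), 0, None))
    z975 = _norm.ppf(0.975)
    hr = np.exp(beta)
    ci = np.column_stack([np.exp(beta - z975 * se),
                          np.exp(beta + z975 * se)])
    with np.errstate(divide="ignore", invalid="ignore"):
        zval = np.where(se > 0, beta / se, np.inf * np.sign(beta))
    pvals = 2.0 * _norm.sf(np.abs(zval))
    return CoxFit(terms=list(names), coefficients=beta, se=se,
                  hazard_ratios=hr, ci95=ci, p_values=pvals,
                  log_partial_likelihood=ll, null_log_likelihood=ll0,
                  n_params=p, n_subjects=n, n_events=n_events, ties=ties)


def _frame_of(data: Union[Cohort, pd.DataFrame]) -> pd.DataFrame:
    return data.df if isinstance(data, Cohort) else data


def fit_cox(data: Union[Cohort, pd.DataFrame], terms: Sequence[str],
            ties: str = "breslow", modified_cutoff: int = 13) -> CoxFit:
    """Fit a Cox model on cohort factors (see :data:`FACTOR_LEVELS`)."""
    df = _frame_of(data)
    X, names = design_matrix(df, terms, modified_cutoff=modified_cutoff)
    return fit_cox_arrays(df["followup_months"].to_numpy(float),
                          df["event"].to_numpy(float), X, names, ties=ties)


# ---------------------------------------------------------------------------
# Univariate screening and the two-step validation
# ---------------------------------------------------------------------------

DEFAULT_FACTORS = ("age_group", "sex", "ethnicity", "histology_grade",
                   "tumor_size_group", "pt_category", "surgery",
                   "n_eighth", "n_modified")


@dataclass
class UnivariateScreen:
    """Per-factor k-group log-rank tests with per-level 5-year OS."""

    factor_tests: pd.DataFrame   # factor, chi2, df, p_value, significant
    level_os: pd.DataFrame       # factor, level, n, os5
    alpha: float

    def significant_factors(self) -> list[str]:
        sig = self.factor_tests[self.factor_tests["significant"]]
        return list(sig["factor"])


def univariate_screen(data: Union[Cohort, pd.DataFrame],
                      factors: Sequence[str] = DEFAULT_FACTORS,
                      modified_cutoff: int = 13,
                      alpha: float = 0.05) -> UnivariateScreen:
    """k-group log-rank test per factor (one chi-square per factor, as a
    multi-level factor contributes a single df = k-1 test)."""
    df = with_derived_factors(_frame_of(data), modified_cutoff)
    t = df["followup_months"].to_numpy(float)
    e = df["event"].to_numpy(float)
    test_rows, os_rows = [], []
    for factor in factors:
        if factor not in FACTOR_LEVELS:
            raise ValueError(f"unknown factor {factor!r}")
        values = df[factor]
        levels = [lv for lv in FACTOR_LEVELS[factor] if (values == lv).any()]
        if len(levels) < 2:
            raise ValueError(
                f"factor {factor!r} has fewer than 2 observed levels")
        groups = []
        for lv in levels:
            mask = (values == lv).to_numpy()
            groups.append((t[mask], e[mask]))
            os_rows.append({
                "factor": factor, "level": lv, "n": int(mask.sum()),
                "os5": survival_at(km_fit(t[mask], e[mask]), 60.0),
            })
        lr = logrank(groups)
        test_rows.append({"factor": factor, "chi2": lr.chi2, "df": lr.df,
                          "p_value": lr.p_value,
                          "significant": bool(lr.p_value < alpha)})
    return UnivariateScreen(factor_tests=pd.DataFrame(test_rows),
                            level_os=pd.DataFrame(os_rows), alpha=alpha)


@dataclass
class TwoStepResult:
    univariate: UnivariateScreen
    step1_fit: CoxFit
    step2_fit: CoxFit
    verdict: dict
    modified_cutoff: int

    def to_frame(self) -> pd.DataFrame:
        """Table-3-style long report."""
        uni = self.univariate
        rows = []
        for _, frow in uni.factor_tests.iterrows():
            factor = frow["factor"]
            for _, lrow in uni.level_os[uni.level_os["factor"] == factor].iterrows():
                rows.append({
                    "factor": factor, "level": lrow["level"],
                    "n": lrow["n"], "os5_pct": 100.0 * lrow["os5"],
                    "univariate_chi2": frow["chi2"],
                    "univariate_p": frow["p_value"],
                })
        out = pd.DataFrame(rows)
        for label, fit in (("step1", self.step1_fit),
                           ("step2", self.step2_fit)):
            hrcol, pcol = f"{label}_hr", f"{label}_p"
            out[hrcol] = np.nan
            out[pcol] = np.nan
            for i, term in enumerate(fit.terms):
                factor, level = term.split("=", 1)
                sel = (out["factor"] == factor) & (out["level"] == level)
                out.loc[sel, hrcol] = fit.hazard_ratios[i]
                out.loc[sel, pcol] = fit.p_values[i]
        return out


def two_step(data: Union[Cohort, pd.DataFrame], modified_cutoff: int = 13,
             ties: str = "breslow", alpha: float = 0.05) -> TwoStepResult:
    """Two-step multivariate validation of the modified N3 split.

    Step 1: univariate-significant factors + the eighth-edition N3 term,
    mN3 excluded.  Step 2: the same terms plus mN3.  The verdict records
    each N term's step-2 Wald p-value against ``alpha``.
    """
    if modified_cutoff == _EIGHTH_CUTOFF:
        raise ValueError(
            "modified_cutoff equals the eighth-edition boundary (15); "
            "the two N3 classifications coincide and the step-2 design "
            "is perfectly collinear")
    df = with_derived_factors(_frame_of(data), modified_cutoff)
    uni = univariate_screen(df, modified_cutoff=modified_cutoff, alpha=alpha)
    sig = [f for f in uni.significant_factors()
           if f not in ("n_eighth", "n_modified")]
    step1_terms = sig + ["n_eighth"]
    step2_terms = step1_terms + ["n_modified"]
    fit1 = fit_cox(df, step1_terms, ties=ties, modified_cutoff=modified_cutoff)
    fit2 = fit_cox(df, step2_terms, ties=ties, modified_cutoff=modified_cutoff)
    verdict = {}
    for factor in ("n_eighth", "n_modified"):
        row = fit2.term_row(factor)
        verdict[factor] = {**row, "retained": bool(row["p_value"] < alpha)}
    return TwoStepResult(univariate=uni, step1_fit=fit1, step2_fit=fit2,
                         verdict=verdict, modified_cutoff=modified_cutoff)
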