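"""Cox partial-likelihood solver, univariate screening, two-step logic."""
import math

import numpy as np
import pytest

from stagecut import (
    ConvergenceError, SimulationConfig, fit_cox, generate, two_step,
    univariate_screen,
)
from stagecut.cox import fit_cox_arrays
from helpers import brute_cox_loglik, cohort_from_arrays


def _random_tied_data(rng, n=150, p=3, censor=0.8):
    X = np.column_stack([rng.integers(0, 2, n).astype(float)
                         if j % 2 == 0 else rng.normal(0, 1, n)
                         for j in range(p)])
    beta = rng.uniform(-0.6, 0.6, p)
    t = np.ceil(rng.exponential(1.0 / (0.08 * np.exp(X @ beta))))
    e = (rng.random(n) < censor).astype(int)
    if e.sum() == 0:
        e[0] = 1
    return X, t, e


class TestSolver:
    def test_identical_survival_binary_coef_zero(self):
        t = np.tile(np.arange(1.0, 21.0), 2)
        e = np.tile(np.r_[np.ones(15), np.zeros(5)], 2).astype(int)
        x = np.r_[np.zeros(20), np.ones(20)]
        fit = fit_cox_arrays(t, e, x, ["grp"])
        assert fit.coefficients[0] == pytest.approx(0.0, abs=1e-10)
        assert fit.hazard_ratios[0] == pytest.approx(1.0, abs=1e-10)

    def test_hr_equals_exp_coef_and_ci_brackets(self, rng):
        X, t, e = _random_tied_data(rng)
        fit = fit_cox_arrays(t, e, X, ["a", "b", "c"])
        np.testing.assert_allclose(fit.hazard_ratios,
                                   np.exp(fit.coefficients), rtol=1e-12)
        assert np.all(fit.ci95[:, 0] <= fit.hazard_ratios)
        assert np.all(fit.hazard_ratios <= fit.ci95[:, 1])

    def test_true_hr2_recovered_without_censoring(self):
        rng = np.random.default_rng(99)
        n = 5000
        x = rng.integers(0, 2, n).astype(float)
        t = rng.exponential(1.0 / (0.05 * np.exp(math.log(2.0) * x)))
        fit = fit_cox_arrays(t, np.ones(n, int), x, ["x"])
        assert 1.85 <= fit.hazard_ratios[0] <= 2.15

    @pytest.mark.parametrize("ties", ["breslow", "efron"])
    def test_loglik_matches_bruteforce(self, ties, rng):
        X, t, e = _random_tied_data(rng, n=60)
        fit = fit_cox_arrays(t, e, X, ["a", "b", "c"], ties=ties)
        brute = brute_cox_loglik(fit.coefficients, X, t, e, ties=ties)
        assert fit.log_partial_likelihood == pytest.approx(brute,
                                                           abs=1e-9)
        brute0 = brute_cox_loglik(np.zeros(3), X, t, e, ties=ties)
        assert fit.null_log_likelihood == pytest.approx(brute0, abs=1e-9)

    @pytest.mark.parametrize("ties", ["breslow", "efron"])
    def test_matches_scikit_survival(self, ties, rng):
        from sksurv.linear_model import CoxPHSurvivalAnalysis
        from sksurv.util import Surv
        for _ in range(10):
            X, t, e = _random_tied_data(rng)
            fit = fit_cox_arrays(t, e, X, ["a", "b", "c"], ties=ties)
            ref = CoxPHSurvivalAnalysis(alpha=0, ties=ties).fit(
                X, Surv.from_arrays(e.astype(bool), t))
            np.testing.assert_allclose(fit.coefficients, ref.coef_,
                                       atol=1e-4)

    def test_wald_invariant_to_reference_relabel(self, rng):
        X, t, e = _random_tied_data(rng, p=1)
        a = fit_cox_arrays(t, e, X[:, 0], ["x"])
        b = fit_cox_arrays(t, e, 1.0 - X[:, 0], ["x_flipped"])
        assert b.coefficients[0] == pytest.approx(-a.coefficients[0],
                                                  abs=1e-7)
        assert b.p_values[0] == pytest.approx(a.p_values[0], abs=1e-7)

    def test_complete_separation_raises(self):
        # x perfectly orders the event times -> monotone likelihood
        t = np.arange(1.0, 41.0)
        e = np.ones(40, int)
        x = np.r_[np.ones(20), np.zeros(20)]
        with pytest.raises(ConvergenceError):
            fit_cox_arrays(t, e, x, ["sep"])

    def test_invalid_ties_rejected(self):
        with pytest.raises(ValueError):
            fit_cox_arrays([1.0, 2.0], [1, 1], [[0.0], [1.0]], ["x"],
                           ties="exact")


class TestFactorInterface:
    def test_fit_cox_on_cohort_factors(self):
        c = generate(SimulationConfig(n=600, seed=21))
        fit = fit_cox(c, ["age_group", "pt_category", "n_modified"])
        assert "age_group=>=65" in fit.terms
        assert "n_modified=mN3b" in fit.terms
        assert fit.n_subjects == 600

    def test_single_level_factor_rejected(self):
        cohort = cohort_from_arrays([1.0, 2.0, 3.0], [1, 1, 0])
        with pytest.raises(ValueError, match="fewer than 2"):
            fit_cox(cohort, ["sex"])  # all male

    def test_unknown_factor_rejected(self):
        cohort = cohort_from_arrays([1.0, 2.0], [1, 1])
        with pytest.raises(ValueError, match="unknown factor"):
            fit_cox(cohort, ["blood_type"])


class TestUnivariateScreen:
    def test_identical_survival_not_significant(self):
        t = [5.0, 10.0, 20.0, 40.0] * 2
        e = [1, 1, 0, 1] * 2
        cohort = cohort_from_arrays(t, e, mln=[10] * 4 + [20] * 4)
        res = univariate_screen(cohort, factors=["n_eighth"])
        row = res.factor_tests.iloc[0]
        assert row["chi2"] == pytest.approx(0.0, abs=1e-9)
        assert not row["significant"]

    def test_planted_age_effect_detected(self):
        """With a planted age log-HR of ln 1.5, the age factor is
        flagged significant in at least 95% of 100 replicates at
        n = 2000."""
        rng = np.random.default_rng(313)
        hits = 0
        reps = 100
        for _ in range(reps):
            seed = int(rng.integers(2 ** 31))
            c = generate(SimulationConfig(
                n=2000, seed=seed, log_hr_step=0.0,
                covariate_effects={"age_ge_65": math.log(1.5)}))
            res = univariate_screen(c, factors=["age_group"])
            hits += bool(res.factor_tests.iloc[0]["significant"])
        assert hits / reps >= 0.95

    def test_per_level_five_year_os_reported(self):
        c = generate(SimulationConfig(n=500, seed=31))
        res = univariate_screen(c, factors=["sex", "pt_category"])
        assert set(res.level_os["factor"]) == {"sex", "pt_category"}
        assert ((res.level_os["os5"] >= 0)
                & (res.level_os["os5"] <= 1)).all()


class TestTwoStep:
    def test_step2_extends_step1_and_ll_increases(self):
        from stagecut import default_paperlike_config
        c = generate(default_paperlike_config(n=1500, seed=77))
        res = two_step(c)
        assert set(res.step2_fit.terms) == set(res.step1_fit.terms) | {
            "n_modified=mN3b"}
        assert (res.step2_fit.log_partial_likelihood
                >= res.step1_fit.log_partial_likelihood - 1e-9)

    def test_verdict_reverses_when_truth_is_at_15(self):
        """Planting the step at the eighth-edition boundary makes the
        eighth term the one retained in the majority of replicates."""
        rng = np.random.default_rng(515)
        reversed_verdicts = 0
        reps = 40
        for _ in range(reps):
            seed = int(rng.integers(2 ** 31))
            c = generate(SimulationConfig(n=2753, seed=seed,
                                          true_cutoff=15,
                                          log_hr_step=math.log(1.6)))
            v = two_step(c).verdict
            reversed_verdicts += (v["n_eighth"]["retained"]
                                  and not v["n_modified"]["retained"])
        assert reversed_verdicts / reps > 0.5

    def test_table3_style_frame(self):
        from stagecut import default_paperlike_config
        c = generate(default_paperlike_config(n=1200, seed=55))
        frame = two_step(c).to_frame()
        assert {"factor", "level", "os5_pct", "univariate_chi2",
                "step1_hr", "step2_hr"} <= set(frame.columns)
        # the mN3 term appears in step 2 only
        mn3b = frame[(frame.factor == "n_modified")
                     & (frame.level == "mN3b")].iloc[0]
        assert np.isnan(mn3b["step1_hr"])
        assert mn3b["step2_hr"] > 0
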