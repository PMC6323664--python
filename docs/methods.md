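# Methods

This note records the statistical conventions, model assumptions and
design decisions behind `stagecut`, in the spirit of a package methods
appendix.  It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Cohort model and eligibility screening

A cohort is a flat table of gastrectomy patients (one row per subject)
in a fixed CSV schema: demographics (age, sex, ethnicity), histology
grade, tumor size, pathological T category, M category, nodes examined,
metastatic-node (MLN) count, surgery type, follow-up in months, a 0/1
death indicator, and four boolean screening flags.  Booleans are stored
as 0/1 and missing values as empty strings; `mln_count <=
lns_examined`, unique ids and enum membership are enforced at
construction.

Screening retains records that satisfy *all* of: gastric primary, age
>= 18, adenocarcinoma, partial or total gastrectomy, > 15 nodes
examined, >= 7 metastatic nodes (pN3), pT1-T4b, M0, follow-up >= 1
month, no multiple primaries, no remnant cancer, and no missing
analytic field.  Because a record can fail several criteria at once,
each exclusion is charged to the **first** failing criterion in that
fixed order; this makes the exclusion report deterministic and ensures
`n_input = n_eligible + sum(exclusions)` exactly.  Two conventions are
worth naming: "survival < 1 month" is implemented as `followup_months <
1` compared numerically (fractional months are allowed), and a missing
tumor size is treated as an incomplete record (screened out) rather
than an error.  A missing value never triggers a content criterion —
it falls through to `incomplete_data` at the end of the order.

Summaries follow registry-table conventions: counts with percentages
rounded half-up to one decimal (so percentages within a variable sum to
100.0 +/- 0.1), mean +/- SD for age, median (range) for tumor size and
node counts.  Between-source comparisons use the uncorrected Pearson
chi-square per categorical level (each level against the rest, which
for a binary variable reproduces the single table p-value) and the
two-sided Mann-Whitney U for continuous variables (reported only when
exactly two sources are present).  The age (< 65 / >= 65) and tumor
size (<= 60 / > 60 mm) dichotomies are computed on demand, never
stored.

## Synthetic cohorts

The generator emulates the features of the pooled registry + hospital
population that the downstream analysis is sensitive to:

* **MLN counts** — negative binomial (mean 12, dispersion 1.6),
  truncated by rejection to [7, 90].  At n = 2753 this yields a median
  of 14, ~8% of patients at exactly 7 MLNs and ~42% above 15, matching
  the shape of the target population.
* **Nodes examined** — MLN count plus a Poisson(12) offset, floored at
  16, so every eligible record clears the "> 15 examined" criterion
  and the median lands near 26.
* **Covariate mix** — sex (61.7% male), ethnicity, grade, pT
  (T4a-weighted), age ~ N(62.4, 13.4²) clipped to [18, 100], tumor
  size log-normal with median 60 mm, surgery type; all as marginal
  probabilities (no dependence between covariates).
* **Survival** — proportional hazards with cumulative hazard
  H(t | x) = h0 * exp(beta' x + gamma * 1[MLN > c*]) * t^shape, with
  exponential baseline (shape = 1) by default: the simplest model that
  satisfies proportional hazards exactly, which keeps Cox
  parameter-recovery tests clean.  A Weibull shape and a secondary
  linear-in-MLN log-HR term are available to probe robustness.  The
  default baseline rate of 0.012/month with paper-magnitude covariate
  effects (age log 1.47, Asian log 0.66, pT up to log 2.18) and a step
  of log 1.6 at c* = 13 puts the five-year OS of the two MLN groups
  near 31% and 14%.
* **Censoring** — administrative at 60 months (survivors have complete
  five-year follow-up), optional exponential random censoring.
  Follow-up is floored at 1 month: the populations this emulates
  exclude peri-operative deaths, so eligible synthetic records always
  clear the one-month criterion.
* **Ineligible planting** — a configurable fraction of records is
  mutated post hoc to violate exactly one randomly chosen screening
  criterion each; their ids are recorded so tests can assert the
  screen removes precisely them.

All draws flow from one `numpy` Generator in a fixed, documented order;
no per-record seeds.  What the generator does **not** emulate —
covariate dependence, calendar-period effects, non-proportional
hazards, informative censoring — bounds what passing tests show about
real registry data: they validate the *procedure* (selection,
validation and comparison behave correctly when a cutoff truly exists),
not any clinical conclusion.

## Survival primitives

Kaplan-Meier and log-rank are implemented from their defining formulas
because the maximal scan *is* the package's core statistic; established
libraries (lifelines, scikit-survival) appear only as independent
cross-checks in the tests.  Conventions:

* a subject censored exactly at an event time remains at risk for that
  event time (standard product-limit convention);
* five-year OS is S(60 months) under the right-continuous step
  convention; queries beyond the last event time return the final
  estimate rather than raising;
* the hypergeometric variance term is zeroed when the risk set holds a
  single subject (the n − 1 denominator vanishes);
* k-group tests use the vector-variance quadratic form on the first
  k − 1 groups (df = k − 1), which for k = 2 reduces to the familiar
  (O − E)²/V statistic;
* zero total events is a documented degenerate result (χ² = 0, p = 1),
  not an error;
* p-values come from the χ² upper tail with no continuity correction.

## Cut-point scan

Candidate cutoffs default to 7–20.  A `min_group` guard (default 20)
skips splits that leave fewer than 20 subjects on either side — the
χ² statistic degenerates for tiny groups; the guard is a package
choice, surfaced as a parameter.  Ties in the maximal χ² break toward
the smallest cutoff, making selection deterministic.  No multiplicity
correction is applied to the selected cutoff's p-value; instead the
acceptance suite quantifies the inflation directly (under the null the
maximal statistic exceeds the fixed-test 95% quantile in far more than
5% of replicates — about 26% under the default study conditions).

## Cox fitting and the two-step validation

The partial likelihood is maximized by Newton-Raphson with analytic
gradient and Hessian, step-halving, and convergence declared when the
log-likelihood gain falls below 1e-10 (relative) with a small gradient.
Tied event times use Breslow's approximation by default — mirroring
the default of the legacy statistical packages such analyses were
historically run in — with Efron's correction behind a flag; both are
validated against scikit-survival to well under 1e-4.  Failure modes
are explicit errors: singular information (collinearity),
non-convergence, and diverging coefficients (|beta| > 20 at or before
convergence), the standard signature of complete separation.  Wald
confidence intervals and p-values come from the inverse observed
information.

Categorical factors are dummy-encoded against fixed reference levels
(age < 65, male, White, G1/G2, <= 60 mm, T1, partial/distal
gastrectomy, N3a, mN3a); only levels observed in the data generate
columns.  Univariate screening uses the k-group log-rank χ² per factor
(one statistic per factor, matching how multi-level factors are
conventionally reported), with significance at p < 0.05.  Step 1 then
fits the univariate-significant factors plus the eighth-edition N3
term (the modified term excluded); step 2 adds the modified term.  The
two N terms disagree only on patients with 14–15 MLNs, so they are
deliberately collinear-but-distinct; no collinearity guard is applied
beyond the separation error, except that a modified cutoff of exactly
15 is rejected up front (the two classifications then coincide and the
step-2 design is singular).  Step-1 factors are evaluated on the
cohort at hand, never hard-coded.

## Staging systems

The (pT, N3a/N3b) → stage table for M0/N3 disease is stored as a
versioned YAML resource (`resources/staging_eighth_n3.yaml`), verified
cell-by-cell against the 8th-edition stage-grouping table, and
validated on load for monotonicity (stage never decreases when N3a →
N3b at fixed pT, nor with advancing pT at fixed N).  The modified
system reuses the same grouping with the N3a/N3b boundary moved to the
scan's selected cutoff, so moving a patient N3a → N3b can only upstage
them.  Empty stage classes are reported with count 0, never dropped.

## System evaluation

Homogeneity is the likelihood-ratio χ² of a Cox model with stage as a
categorical factor (df = non-empty stages − 1); discrimination /
gradient monotonicity is the corresponding 1-df statistic with stage
entered as a consecutive-integer score in the declared order (the LR
form by default; a score-test variant is behind a flag, and the two
differ negligibly).  AIC is −2 logPL + 2k with k = the categorical
model's coefficient count — no small-sample correction, matching the
conventional usage of these metrics.  Since the scored model is nested
in the categorical one, trend χ² ≤ LR χ² always; and when two systems
produce the same number of non-empty stages their AIC margin equals
minus their LR-χ² margin exactly (shared null likelihood) — both
identities are asserted in the tests, the AIC identity against a
brute-force risk-set-loop recomputation of the log partial likelihood.

## Pipeline

`run_pipeline` sequences screen → summarize → scan → three-band →
restage (eighth + modified at the selected cutoff) → two-step →
evaluation, writing Table-1/2/3/4-style TSVs, KM exports, a screening
report, a MANIFEST and a run log with seed and library versions.  The
modified cutoff flows from the scan (a `force_cutoff` option pins it);
if it lands on 15 the three-band and two-step stages are skipped with a
logged note, since the modified and eighth systems then coincide.  A
stage failure preserves partial outputs, marks the MANIFEST incomplete
and raises an error naming the stage.  Outputs are deterministic:
identical config and seed give byte-identical TSVs (the run log, which
carries wall times, is the only exception).

## Problem sizes in the test and acceptance suites

Monte-Carlo checks use the study-condition sizes: cutoff recovery at
n = 2000 over 200 replicates; two-step verdict and three-metric win
rates at n = 2753 over 100 replicates; null calibration and
maximal-selection inflation at n = 400 over 500 replicates; Cox-oracle
agreement over 50 random tied cohorts per tie method.  Replicate seeds
are spawned from one root generator so every rate is reproducible.

## Known limitations

* The generator's covariates are marginally, not jointly, realistic;
  source-specific structure (e.g. ethnicity confined to one arm) is not
  emulated.
* Proportional-hazards diagnostics, weighted log-rank variants, KM
  confidence bands, permutation-adjusted p-values for the maximal
  statistic, and concordance-type discrimination indices are out of
  scope.
* The Wald p-values in step 2 ignore the selection of the cutoff in
  the same data; the package reports them as the procedure defines
  them, and quantifies the selection effect only under the null.
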