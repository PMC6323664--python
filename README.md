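# stagecut

Survival cut-point optimization and staging-system evaluation for
node-positive (N3) gastric cancer cohorts.

## The problem

Gastric cancer with at least 7 metastatic lymph nodes (MLNs) is staged
N3 and, under the 8th-edition UICC/AJCC TNM classification, split into
N3a (7–15 MLNs) and N3b (> 15 MLNs) for final pathological staging.
Whether 15 is actually the MLN count that best separates prognoses is
an empirical question.  `stagecut` implements, as a tested reusable
pipeline, the procedure for answering it on any patient-level cohort:

1. **Eligibility screening** — registry-style inclusion/exclusion
   criteria (gastric adenocarcinoma, gastrectomy, > 15 nodes examined,
   pN3 M0, ≥ 1 month of follow-up, …) applied in a fixed order with a
   reconciling exclusion report.
2. **Cut-point scan** — for every candidate cutoff *c* (default 7–20),
   split the cohort at MLN ≤ *c* vs > *c* and compute the two-group
   log-rank statistic

   χ²(c) = ( Σⱼ (O₁ⱼ − E₁ⱼ) )² / Σⱼ Vⱼ ,   Vⱼ = n₁ⱼn₂ⱼdⱼ(nⱼ−dⱼ) / (nⱼ²(nⱼ−1)),

   selecting the *c* with maximal χ² (a maximally selected rank
   statistic; the package's test suite documents the null inflation this
   induces).  Kaplan-Meier curves supply the 5-year overall survival of
   each split.
3. **Three-band analysis** — patients the new split reassigns (e.g.
   14–15 MLNs when the scan selects 13) are compared against both
   neighboring bands by pairwise log-rank tests.
4. **Two-step Cox validation** — step 1 fits the univariate-significant
   covariates plus the 8th-edition N3a/N3b term; step 2 adds the
   modified term.  The classification whose term retains Wald p < 0.05
   in step 2 carries the independent prognostic information.
5. **Staging-system comparison** — the cohort is restaged under both
   (pT, N3a/N3b) → {IIB, IIIA, IIIB, IIIC} groupings and compared by
   likelihood-ratio χ² (homogeneity), linear-trend χ²
   (discrimination/monotonicity) and AIC = −2 logPL + 2k (parsimony).

A synthetic-cohort generator with a *plantable true cutoff* (step
proportional-hazards model with Table-1-like covariate mix and five-year
administrative censoring) makes every stage testable without access to
registry data.

The Kaplan-Meier, log-rank and Cox partial-likelihood (Breslow/Efron
ties) machinery is implemented from the defining formulas and is
cross-checked in the test suite against lifelines and scikit-survival.

## Worked example

Generate a cohort of 2753 patients with the hazard stepping by
HR 1.6 above 13 MLNs, then run the analysis:

```sh
$ stagecut simulate --n 2753 --seed 7 --out cohort.csv
wrote 2753 records to cohort.csv

$ stagecut scan --input cohort.csv --range 7:20 --out scan.tsv
selected cutoff 13 (chi2 = 95.718)

$ stagecut twostep --input cohort.csv --cutoff 13
n_eighth: HR 0.99 (0.86-1.14), p = 0.8507, retained = False
n_modified: HR 1.56 (1.35-1.80), p = 1.515e-09, retained = True

$ stagecut evaluate --input cohort.csv --cutoff 13
  system  trend_chi2      trend_p    lr_chi2  lr_df         lr_p          aic  n_subjects  n_events
  eighth   86.948927 1.113601e-20  89.253519      3 3.168720e-19 31291.184218        2753      2133
modified  107.586905 3.310655e-25 112.038898      3 3.994961e-24 31268.398839        2753      2133
overall better system: modified
```

Reading the output: the scan recovers the planted cutoff 13 as the
maximal-χ² split.  In step 2 of the Cox validation the modified N3b
term keeps an independent hazard ratio of 1.56 (p < 0.001) while the
8th-edition term collapses to HR 0.99 (p = 0.85) — once "> 13 MLNs" is
in the model, "> 15 MLNs" adds nothing.  Restaging under the modified
boundary improves all three system-level metrics: higher LR χ²
(112.0 vs 89.3), higher trend χ² (107.6 vs 86.9) and lower AIC
(31 268 vs 31 291).

`stagecut run --config run.yaml` executes the whole flow (screening →
summaries → scan → three-band → restaging → two-step → evaluation) and
writes a deterministic TSV report bundle; see
`stagecut.pipeline.PipelineConfig` for the YAML schema.

## Layout

| module                 | role                                            |
|------------------------|-------------------------------------------------|
| `stagecut.cohort`      | data model, CSV I/O, screening, summaries       |
| `stagecut.simulate`    | synthetic cohorts with a plantable cutoff       |
| `stagecut.survival`    | Kaplan-Meier and log-rank from first principles |
| `stagecut.cutpoint`    | maximal-χ² scan, three-band analysis            |
| `stagecut.cox`         | partial-likelihood solver, two-step validation  |
| `stagecut.staging`     | N3 subcategories, TNM stage grouping (YAML)     |
| `stagecut.evaluation`  | LR χ² / trend χ² / AIC system comparison        |
| `stagecut.pipeline`    | end-to-end orchestration and report bundle      |
| `stagecut.cli`         | `stagecut` command-line entry point             |

See `docs/methods.md` for the statistical conventions, generator
assumptions and design choices.
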