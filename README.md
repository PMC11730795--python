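# dxmetrics

Diagnostic test accuracy from subject-level data: 2×2 confusion tables,
sixteen accuracy measures with confidence intervals, empirical ROC and
precision–recall curves, and combined multi-test reports.

## Who this is for

Laboratory scientists and epidemiologists comparing one or more candidate
diagnostic tests (a new specimen type, a cheaper assay, a classifier's
predicted probabilities) against a reference ("gold standard") test, where
both are recorded as continuous measurements and dichotomized at a clinical
cutoff — e.g. HIV viral load with virologic failure defined as ≥ 1000
copies/mL, or machine-learning risk scores thresholded at 0.5. All tests are
evaluated against the same reference and assembled into one report, so
multiple assays or models can be compared side by side.

## The statistics

Each test variable is cross-classified against the dichotomized reference:

|              | truth + | truth − |       |
|--------------|---------|---------|-------|
| **test +**   | a (TP)  | b (FP)  | n₁    |
| **test −**   | c (FN)  | d (TN)  | n₂    |
| **total**    | m₁      | m₂      | n     |

From these cells the package computes sensitivity a/m₁, specificity d/m₂,
PPV a/n₁, NPV d/n₂, the four complementary error rates (FPR, FNR, FOR, FDR),
likelihood ratios LR+ = sens/(1−spec) and LR− = (1−sens)/spec, overall
accuracy (a+d)/n, prevalence m₁/n, the diagnostic odds ratio ad/bc, Cohen's
kappa (p₀−p‌ₑ)/(1−pₑ), Youden's J = sens + spec − 1, and the F-score
2a/(2a+b+c).

Binomial confidence intervals for the proportion-scale measures are
selectable: Wald normal approximation p̂ ± z·√(p̂(1−p̂)/n) (default), the
Wilson score interval, or the exact Clopper–Pearson interval from beta
quantiles. Ratio measures use log-scale normal intervals (Simel standard
errors for the likelihood ratios, Woolf for the DOR); kappa uses its
asymptotic standard error. Empirical ROC and PR curves are swept over every
distinct observed score with trapezoidal AUROC (identical to the
Mann–Whitney statistic) and AUPRC.

## Worked example

The cell counts below are from a published comparison of dried blood spots
prepared with microcapillary tubes (M-DBS) against plasma for HIV viral-load
testing, dichotomized at 1000 copies/mL:

```python
from dxmetrics import AnalysisConfig, build_panel, table_from_counts
from dxmetrics.report import ReportSpec, render_markdown

table = table_from_counts(213, 26, 23, 480)
config = AnalysisConfig(truth_cut=1000, test_cut=1000)   # Wald CIs, alpha 0.05
panel = build_panel(table, config, test_name="M-DBS VL", reference_name="plasma VL")
print(render_markdown([panel], ReportSpec(table_name="dbs")))
```

prints (abridged):

```
| Test     | Test result | plasma VL + | plasma VL - | Total | Measure                          | Estimate (CI)    |
| M-DBS VL | >= cut      | 213         | 26          | 239   | Sensitivity (%)                  | 90.3 (86.5–94.0) |
|          | < cut       | 23          | 480         | 503   | Specificity (%)                  | 94.9 (92.9–96.8) |
|          | Total       | 236         | 506         | 742   | Positive Predictive Value (PPV) (%) | 89.1 (85.2–93.1) |
|          |             |             |             |       | Positive Likelihood Ratio (LR+)  | 17.6 (12.1–25.6) |
|          |             |             |             |       | Diagnostic Odds Ratio (DOR)      | 171.0 (95.4–306.5) |
|          |             |             |             |       | Youden's Index                   | 0.9 (0.8–0.9)    |
```

Read: the DBS assay detects 90.3% of subjects in virologic failure and
correctly clears 94.9% of those who are not; a positive DBS result raises
the odds of failure 17.6-fold. The same pipeline runs from the shell on a
subject-level CSV:

```bash
dxmetrics --data study.csv --truthvar plasma_vl --truthcutvalue 1000 \
          --testvarlist "mdbs_vl vdbs_vl" --testcutvalue 1000 \
          --outputdir out --tablename dbs --varmethod normal --plots
```

writing `dbs_table.md`/`.html`, a tidy `dbs_dams.csv` with unrounded
estimates, ROC/PR curve tables and overlay plots with AUC legends.

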