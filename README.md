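# markerpipe

Discovery and clinical validation of **bimodal prognostic expression
markers** in acute myeloid leukemia (AML), as a reusable Python pipeline.

Risk stratification in AML rests on cytogenetics and a handful of mutations,
yet leaves a large intermediate-risk group where the best consolidation
therapy (chemotherapy vs allogeneic transplant) is unclear. Single genes
with a *bimodal* expression pattern — a low-expressing and a
high-expressing patient subgroup separated by an order of magnitude — make
attractive clinical tests: the two modes can be told apart by a cheap
RT-qPCR assay with a single cutoff. This package implements the complete
analysis chain for such markers:

1. **Genome-wide screen** (`markerpipe.screen`): for every gene in an
   RPKM-scale expression matrix, split patients at the 75th percentile of
   expression and log-rank-test overall survival; keep genes with a bimodal
   distribution (two-component Gaussian mixture on log10 values, BIC
   margin), ≥ 10-fold mode separation, and a high-mode median above 1 RPKM;
   rank by log-rank p.
2. **RT-qPCR quantification** (`markerpipe.qpcr`): plasmid standard curves
   (OLS of Cq on log10 copies), copy-number conversion, and normalized copy
   numbers `NCN = 100 × target / ABL1-control`.
3. **Cutoff selection** (`markerpipe.threshold`): ROC curves over observed
   NCN values with the ≥ calling rule and the Youden index
   J = sensitivity + specificity − 1; samples with NCN ≥ cutoff are `H+`.
4. **Survival validation** (`markerpipe.survival`, `.regression`,
   `.report`): Kaplan–Meier/log-rank for OS and RFS, Aalen–Johansen
   cumulative incidence and Gray's test for relapse with death as a
   competing risk, Fisher's exact contingency tables, logistic regression
   for induction failure, Cox models with age (linear + quadratic), WBC,
   cytogenetic risk, NPM1/FLT3-ITD and their interaction, allogeneic
   transplant as a **time-dependent covariate**, a spline-based
   proportional-hazards check, and the Lunn–McNeil stacked-data
   competing-risks Cox extension.
5. **Synthetic cohorts** (`markerpipe.synthetic`): every stage is exercised
   against generated data with known planted structure — a bimodal gene with
   configurable prevalence and fold separation, cause-specific exponential
   event times whose hazards depend on marker status, and qPCR plates from
   known standard curves.

## Worked example

```bash
markerpipe simulate --out-dir demo --n-genes 50 --seed 7
markerpipe quantify --wells demo/qpcr_wells.csv --out demo/ncn.csv
# TARGET: slope=-3.310 intercept=39.93 r2=0.9997 efficiency=100.51%
# CONTROL: slope=-3.458 intercept=38.06 r2=0.9994 efficiency=94.62%
markerpipe validate --clinical demo/clinical.csv --ncn demo/ncn.csv \
    --cutoff 1100 --out-dir demo/report
```

The validation report for this simulated 358-patient cohort prints (among
other fields):

```json
{
  "n": 358,
  "n_high": 99,
  "os_H+_3y": 0.268,
  "os_H-_3y": 0.481,
  "os_logrank_p": 9.4e-06,
  "cr_marker_or": 1.68,
  "os_marker_hr": 1.60,
  "rfs_marker_hr": 1.49
}
```

Reading: 99 of 358 samples called marker-high at the 1100-NCN cutoff;
their 3-year overall survival is 27% against 48% for marker-low patients
(log-rank p ≈ 1e-5), and after adjustment for age, WBC, cytogenetic risk,
NPM1/FLT3-ITD and time-dependent transplant, marker-high status carries an
OS hazard ratio of 1.60. The numbers vary with the simulation seed; the
planted effects behind them are an odds ratio of 3.08 for induction
failure and hazard ratios of 1.68 (death) and 1.67 (relapse).

The same steps are available as library calls (`generate_expression`,
`quantify_plate`, `screen_genes`, `youden_threshold`, `cox_fit`, ...); see
the module docstrings and `docs/methods.md`.

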