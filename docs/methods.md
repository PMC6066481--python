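# Methods

This note documents the statistical models, the synthetic-data design, the
numerical choices and the known limitations of `markerpipe`.

## The screening model

For each gene the screen dichotomizes samples at the 75th percentile of
expression (linear interpolation between order statistics; values tied
with the threshold are called high, matching the ≥ rule used for the assay
cutoff) and compares overall survival between the groups with the
two-sample log-rank test. Candidate markers must additionally look like
usable clinical tests:

* **Bimodality** is operationalized as model selection between one- and
  two-component Gaussian mixtures on log10 expression, with two components
  accepted when BIC improves by more than a margin of 2 (a configurable
  `ScreenConfig.bic_margin`). The mixture is fitted by a deterministic EM
  (quantile-split initializations at the 25th/50th/75th percentiles,
  per-sample tolerance 1e-5); determinism keeps the screen reproducible
  without a seed, and a vectorized batch path fits all genes
  simultaneously. Zeros are replaced by half the smallest positive value
  before the log transform. Two guards keep the two-component fit from
  manufacturing modes out of tail outliers — the well-known degenerate-EM
  pathology where a component collapses onto a couple of points and its
  density spike wins any likelihood comparison: component standard
  deviations are floored at 0.01 on the log10 scale, and a bimodal call
  additionally requires both mixture weights to reach 5% of samples
  (`ScreenConfig.min_component_weight`) — a clinical "subgroup" of two
  patients is not a mode.
* **Fold separation**: the ratio of the back-transformed component medians
  must reach 10. With a *true* separation of exactly 10-fold the estimate
  straddles the threshold, which is the intended behavior of a hard
  criterion; the ranking does not depend on it (passing genes are ranked
  first, then the rest, each block by log-rank p).
* **Peak expression**: the high-component median must exceed 1 RPKM
  (strictly), so that the high mode is measurable by a targeted assay.
* **Dynamic range** p99 / (p1 + 0.01 RPKM) is reported but not filtered on
  by default, since no principled threshold exists; it can be switched on
  via `ScreenConfig.dynamic_range_threshold`.

No multiple-testing correction enters the primary ranking — the screen is a
discovery ranking, not an inference — but a Benjamini–Hochberg column is
included for reference.

## qPCR quantification

Standard curves are ordinary least squares of Cq on log10 plasmid copies
(at least three distinct dilution levels; a non-negative slope raises an
error since Cq must fall as template rises). Amplification efficiency is
reported as `E = 10^(−1/slope) − 1`. Unknown wells are averaged on the Cq
scale across replicates (replicate SD kept for QC), inverted through the
curve, and normalized as `NCN = scale × target/control` with `scale = 100`
(the Europe-Against-Cancer reporting convention for transcripts normalized
on a control gene such as ABL1; configurable). A sample whose control gene
fails to amplify is flagged non-evaluable rather than given an infinite
NCN.

## Cutoff selection

ROC curves are computed over the observed score values with the ≥ calling
rule, so the selected Youden cutoff is directly usable as the assay's
dichotomization rule (`NCN ≥ cutoff → H+`, boundary inclusive). Ties in
the maximal J resolve to the smallest qualifying threshold (the more
sensitive test). The default ROC outcome is death by 3 years among
patients whose follow-up could have reached 3 years; patients censored
earlier are excluded because their status is unknown. AUC is trapezoidal
and equals the Mann–Whitney U probability. The published cutoff of
1100 NCN is consumed as a constant (`PUBLISHED_CUTOFF_NCN`) by the
validation stage; the package does not claim to re-derive it.

## Survival and competing-risks estimators

Kaplan–Meier with Greenwood variance and the log-rank test use the
standard convention that events precede censorings at tied times. The
cumulative incidence of relapse treats death without relapse as a
competing risk (Aalen–Johansen estimator; delta-method variance in the
Aalen form, which reduces to Greenwood's formula for 1 − KM when only one
cause exists). Gray's test for equality of subdistribution hazards is
implemented as the Fine–Gray weighted score: subjects who failed from the
competing cause remain in the risk set with weight `G(t−)/G(T_i−)` (G =
censoring Kaplan–Meier), and the score variance is estimated from
per-subject influence contributions. A label-permutation p-value mode
(`n_permutations=`) provides an exact reference under exchangeability.
Against the reference R implementation (cmprsk) the chi-square statistic
agrees to a few percent on fixtures, and the type-I error over 1,000 null
simulations at n = 100 was 0.047.

All p-values are two-sided from the chi-square reference.

## Regression models

* **Induction response**: logistic regression (statsmodels) of *failure*
  of complete remission, so the marker's adjusted OR > 1 means a higher
  probability of refractory disease.
* **Cox models**: a counting-process partial-likelihood Newton solver with
  Efron tie handling, delayed entry and strata (validated coefficient-,
  SE- and log-likelihood-wise against lifelines). Transplant enters
  time-dependently: a patient's HSCT indicator switches 0 → 1 at the
  transplant date inside their follow-up interval, which avoids
  immortal-time bias.
* **Covariates**: age is centered and scaled per decade and enters with
  linear plus quadratic terms; the two coefficients are reported jointly
  (a 2-df Wald test) because neither is interpretable alone. WBC enters
  either as the categories <50 / 50–99 / ≥100 ×10⁹/L or as log WBC.
  Cytogenetic risk uses favorable as reference; patients with undetermined
  cytogenetics (~1%) are excluded from risk-adjusted models because the
  stratum is too small to estimate and produces quasi-separation.
  NPM1 and FLT3-ITD enter with their interaction. Complete-case analysis
  throughout, with the number of dropped rows logged and reported.
* **Proportional hazards check**: each covariate is interacted with
  `[log t, rcs(log t)]` — a restricted cubic spline with 3 knots at the
  10th/50th/90th percentiles of event log-times — on data episode-split at
  the distinct event times, and compared to the PH model by likelihood
  ratio (2 df). With fewer than 20 events the spline is dropped for a
  linear-in-log-time interaction (1 df).
* **Competing risks**: the Lunn–McNeil fit stacks one stratum per cause
  (other causes censored), interacts every covariate with the cause
  stratum, and fits a single stratified Cox model; with unshared
  coefficients this is algebraically identical to separate cause-specific
  fits, which the test suite asserts.

Wald confidence intervals (`exp(β ± 1.96 se)`) are used throughout,
matching the usual reporting style for adjusted ORs/HRs. Newton iteration
stops when the gradient falls below 1e-8 relative to the log-likelihood
*or* the Newton step falls below 1e-6 relative to the coefficients — the
second criterion matters at n ≈ 10⁴, where round-off in the cumulative
risk-set sums leaves gradient noise of order 1e-3 that the first criterion
alone cannot get under.

## Synthetic cohort design

The generator emulates a 358-patient training cohort with a planted
bimodal marker:

* **Expression**: background genes are log-normal with a common location
  (default median 0.5 RPKM, SD 0.25 on log10); each planted gene is a
  two-component mixture whose low mode coincides with the background and
  whose high mode sits `fold_separation` (default 10) above it, with
  high-mode prevalence 0.223. One latent high/low assignment is shared by
  all planted genes and returned as ground truth.
* **Clinical outcomes**: complete remission is Bernoulli from a logistic
  model with baseline CR probability 0.834 (the marker-low rate of the
  emulated cohort) and failure odds multiplied by `marker_or_cr`
  (default 3.08) for marker-high patients. After CR, relapse and death
  without relapse are independent cause-specific exponentials (defaults
  0.0006 and 0.0005 per day) whose hazards are multiplied by
  `marker_hr_relapse` (1.67) and `marker_hr_death` (1.68); the earlier
  time is realized, giving closed-form cumulative incidence functions for
  testing. Patients who relapse die at twice the baseline death hazard;
  patients who never achieve CR die at three times. These two multipliers
  are not part of the competing-risks contract — they exist so that overall
  survival is defined for every patient — and were fixed once so that the
  marker-low/marker-high 3-year OS lands near the cohort the generator
  emulates (≈ 0.49 / 0.19 at defaults). Censoring is exponential
  (0.0002/day) from the relevant origin; transplant dates are drawn
  uniformly inside (CR, end of follow-up) for a fraction (default 0.25) of
  CR patients, which makes a valid time-dependent covariate with no
  immortal-time artifact. Covariates (age, WBC, cytogenetics, mutations)
  are drawn at plausible AML frequencies but are independent of outcome by
  default, so planted effects remain the only signals.
* **Marker assay values**: NCN-scale values are log-normal around a low
  mode of 350 with the same fold separation, placing the geometric
  midpoint of the modes near the published 1100-NCN cutoff.
* **qPCR plates**: Cq = slope·log10(copies) + intercept + N(0, sd) for a
  standard dilution series (10² … 10⁷, duplicate wells) plus unknown wells.

All dates are day offsets from diagnosis; the generators are deterministic
given `CohortConfig.seed`.

What the generator does **not** emulate: covariate–outcome confounding
(mutations and cytogenetics carry no prognostic effect unless planted),
calendar-time accrual, cure fractions, non-exponential censoring, or
correlated background genes. Passing tests therefore demonstrate that the
estimators recover what was planted under clean sampling assumptions, not
that the pipeline is robust to every pathology of real cohort data.

A consequence of the mixed baseline hazards worth knowing: with the marker
affecting only the death hazard, the *marginal* OS hazard ratio estimated
by Cox regression is mildly attenuated relative to the planted
per-stratum ratio (≈ 1.59 observed at a planted 1.68 over 25 seeds of
n = 10,000) because the high-hazard strata (refractory, post-relapse)
deplete faster in the marker-high arm. This is the familiar
marginal-vs-conditional non-collapsibility of hazard ratios, not an
estimation bias; the recovery stays well inside the 10% band used by the
acceptance checks.

## Problem sizes

Simulation-based checks use the sizes at which their Monte-Carlo error is
comfortably below the tolerance being asserted: effect-size recovery at
n = 10,000–20,000 over 25 seeds, screen recovery at the cohort's native
scale (358 samples × 2,000 genes) over 50 seeds, null calibrations over
200–500 replicates at n = 100–150, and permutation references at 20,000
permutations for n ≤ 40. These choices keep each check to a few minutes on
one core.

## Known limitations

* Gray's test uses the influence-function variance of the Fine–Gray score
  rather than the original closed-form variance; the two agree on fixtures
  but are not algebraically identical. The permutation mode is the fallback
  arbiter.
* The PH check's spline basis (3 knots in log time) is one reasonable
  flexible-time-dependence choice among several; knot placement is not
  exposed as a user option.
* `summarize_cohort` handles categorical variables only; continuous
  variables must be categorized by the caller.
* Multi-plate qPCR batch calibration and amplification-curve processing
  are out of scope; Cq values are taken as given.
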