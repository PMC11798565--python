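# Methods

## The estimation problem

A screening classifier applied to a population survey over-counts a rare
disorder: most of its positives are false positives from far more common
conditions that resemble the target class, and it also misses a fraction of
true cases. `prevadjust` implements the resulting two-step estimate of
schizophrenia prevalence from a quota-matched web survey:

1. **Crude prevalence** — the fraction of the n sampled respondents the
   classifier labels positive, `N_crude / n`.
2. **Adjusted prevalence** — remove the expected false positives
   contributed by three "confuser" classes (respondents without mental
   disorders, MDD patients, BD patients), restore the expected false
   negatives, and renormalise:

   ```
   N_fp = (P_hc·r_hc + P_MDD·r_MDD + P_BD·r_BD) · n
   N_tp = N_crude − N_fp
   N_fn = N_tp / p              where p is the TP:FN ratio
   P_population = (N_crude − N_fp + N_fn) / n
   ```

This is a Rogan–Gladen-style misclassification adjustment in which the
specificity deficit is decomposed by confuser class. All plug-in constants
are treated as known: the population proportions `P_hc = 0.80`,
`P_MDD = 0.079`, `P_BD = 0.004` come from literature reviews; the
false-positive rates `r_hc = 0.031`, `r_MDD = 0.554`, `r_BD = 0.594` and the
ratio `p = 46/15` (equivalently, sensitivity `p/(1+p) = 46/61 ≈ 0.754`)
from the classifier's internal and external validation. The package's
default `MisclassificationProfile` carries exactly these values; with a
crude count of 62 among n = 750 it gives `N_fp = 53.2065 → 53`,
`N_tp = 9`, `N_fn = 2.935 → 3`, adjusted prevalence `12/750 = 1.6%`.

### Rounding and degenerate inputs

- The per-class false-positive components (18.60, 32.82, 1.78 at the
  default profile) are reported **unrounded**; only the summed `N_fp` is
  rounded, half away from zero. No single rounding rule makes the three
  rounded components and their rounded sum mutually consistent, so the
  package never rounds components.
- `N_fn` is rounded half away from zero as well.
- If `N_fp > N_crude` (possible in bootstrap replicates or when the true
  prevalence is near zero), `N_tp` clamps to 0 with a recorded warning and
  the reported adjusted prevalence clips to [0, 1]. The clamp truncates
  the estimator's lower tail, so its *mean* is biased upward near zero
  prevalence: by exact binomial enumeration, about +0.32 percentage points
  at a true prevalence of 0.5% with n = 750. Bias and recovery
  experiments therefore average the **unclamped linear estimator**
  (`adjusted_prevalence_array(..., clamp=False)`), whose residual bias
  (from integer rounding of `N_fp`) is under 0.05 percentage points at all
  prevalences studied. Reported single-survey estimates stay clamped.
- In the 2×2 adjusted confusion table the predicted-positive row always
  splits the observed `N_crude` into `(N_tp, N_crude − N_tp)`, which caps
  the false-positive cell at the observed positives.

## Study design

The sample size comes from the single-population-proportion formula
`n = Z²·p(1−p)/e²` with Z = 1.96, assumed prevalence p = 0.02 and margin
e = 0.01: 753, rounded to a recruitment target of 750. Respondents are
recruited per demographic cell — 5 age groups × 2 genders × 13 Japanese
regions (130 cells) — with cell targets apportioned from a population
composition table by **largest-remainder allocation**: each cell gets the
floor of its proportional share and leftover units go to the largest
fractional remainders, ties broken by canonical cell order. Every count is
within 1 of exact proportionality and the counts sum exactly to n.

Age-group boundaries are not part of the published design; the package
defaults to decade bins closed at the stated 20–75 range
(20–29, …, 50–59, 60–75), configurable through the composition table. The
shipped composition table is **synthetic** (a product of plausible age,
gender and region marginals for the Japanese adult population); any
user-supplied `age_group, gender, region, proportion` CSV replaces it.

## Synthetic cohorts

The real web-panel data is proprietary, so the `cohort` module simulates
it. Panel members carry a demographic cell (iid from the composition), a
latent diagnostic class (iid from a `PopulationMix`; default 80% healthy,
7.9% MDD, 0.4% BD, 1.6% schizophrenia, 10.1% other mental disorders — the
correction profile's proportions with the residual class closing the
simplex), and survey features drawn from class-conditional distributions
defined by a `FeatureSchema`.

The default schema spans the five survey feature categories (demographics,
health background, physical, psychiatric and social comorbidities) with
continuous (normal), ordinal (binomially generated integer codes) and
categorical (per-class probability vectors) variables. Its class
separations were calibrated once so that a linear classifier distinguishes
schizophrenia from healthy respondents with a cross-validated AUC in the
mid-0.80s — the level the real classifier reported in internal
validation — with MDD and BD placed close to schizophrenia so they are
frequently confused with it, as external validation found. A
`null_schema()` variant removes all class separation for negative
controls.

What the generator does *not* emulate: item non-response (the survey
enforced completeness), panel participation behaviour, correlations
between features beyond those induced by the latent class, and any real
marginal distribution of the Japanese population. Passing tests therefore
demonstrate the estimator's statistical behaviour under its own
assumptions, not the realism of the synthetic data.

## Classifier

The published screening model is a multilayer perceptron with five hidden
layers of 128, 64, 32, 16 and 8 ReLU units, He-normal initialisation
(weights ~ N(0, 2/fan_in), zero biases) and a logistic output unit. The
package implements this architecture in numpy, with training choices the
publication does not report supplied as defaults: weighted binary
cross-entropy (inverse class frequency), minibatch Adam (learning rate
1e-3, batch 32), early stopping on a 20% stratified validation split
(patience 10) with best-weight restoration, z-standardisation of numeric
and one-hot encoding of categorical features learned on the training split
only. The decision threshold is 0.5 with `≥` at the boundary. All of
these are configurable (`Hyperparams`), and all runs are seeded.

Because no trained weights for the real model exist, the pipeline also
provides a **rate-based oracle classifier**: each respondent is labelled
positive with the probability attached to their latent class (default: the
published per-class rates — 0.031 healthy, 0.554 MDD, 0.594 BD, 46/61
schizophrenia, 0 other). The oracle reproduces the validation error
structure exactly in expectation and isolates the correction stage from
classifier training.

Evaluation reports the Mann–Whitney (tie-corrected) AUC via scikit-learn,
accuracy/sensitivity/specificity at the threshold, and stratified k-fold
cross-validation with per-fold AUCs.

In `trained` pipeline mode with no explicit profile, the correction's
plug-in rates are the trained model's own per-class positive rates
measured on a held-out synthetic cohort (2000 healthy + 500 of each other
class), with `p` set to the measured sensitivity odds — mirroring how the
real study obtained its rates from external validation. Note the
correction formula ignores false positives from the residual "other"
class by construction; when a trained model flags many "other"
respondents, the adjusted estimate remains inflated. This is a faithful
property of the published formula, visible in trained-mode runs.

## Bootstrap intervals

Intervals resample the n individual case indicators with replacement
(10,000 replicates by default); the replicate positive count is therefore
a Binomial(n, p̂) draw, which is generated directly. Two interval types:

- `normal_boot` (default): point ± 1.96 × (replicate SD). Applied to the
  750 indicators with 12 adjusted cases positive it gives 0.7%–2.5% at one
  decimal percent.
- `percentile_boot`: empirical 2.5/97.5 percentiles.

Bounds clamp to [0, 1]. `bootstrap_corrected_ci` additionally re-applies
the whole correction inside every replicate (resampling respondent rows),
so the interval reflects the correction's discreteness. The published
*crude* interval (6.6%–10.1%) is narrower than any indicator-level
resampling scheme yields (≈6.3%–10.3%); the underlying bootstrap design
is not documented, so the package makes no attempt to match it and reports
its own intervals for the crude estimate.

Measured properties (all recomputed by the test suite): the nominal 95%
normal-bootstrap interval covers a true prevalence of 0.016 at n = 750 in
93–97% of simulated surveys; percentile and normal intervals agree within
0.5 percentage points for case counts ≥ 30; width shrinks with n.

## Problem sizes used by the validation suite

The packaged experiments use 200 simulated surveys per prevalence for
parameter recovery (panel 15,000 → quota sample 750), 1000 simulated
surveys for coverage, 10,000 bootstrap replicates throughout, and
development sets with the published 223/1776 case balance. These sizes
give Monte-Carlo standard errors comfortably below the tolerances being
checked while keeping a full run in tens of seconds.

## Known limitations

- The plug-in rates are constants; their sampling uncertainty (e.g. the
  46:15 ratio comes from only 61 externally validated cases) is not
  propagated, exactly as in the source procedure.
- The clamped point estimator is upward-biased near zero prevalence (see
  above); the package exposes the unclamped estimator for bias studies.
- The correction cannot remove false positives from diagnostic classes
  outside {healthy, MDD, BD}.
- Synthetic features are conditionally independent given the latent
  class; real survey items are not.
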