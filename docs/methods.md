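# Methods

## Synthetic cohort model

The generator emulates a longitudinal population-based cohort of older
adults (default n = 1986, ~3.4% ten-year incidence of open-angle glaucoma)
with seven clinical baseline variables and additive genotypes at seven risk
SNPs. It has two modes:

* **Prospective** (default): covariates are drawn from the control-group
  distributions — controls are 96.6% of the cohort, the closest available
  proxy for the source population — genotypes from Hardy–Weinberg
  equilibrium at the control risk-allele frequencies, and incident status
  from the logistic model. This mode is the basis of all parameter-recovery
  tests, because the generating coefficients are the estimand.
* **Retrospective**: the case/control split is fixed first (default 67 /
  1919) and covariates/genotypes are drawn from the group-specific
  distributions, so realized group summaries converge to the configured
  marginals. This mode is the basis of frequency and baseline-table tests.

Distributional choices:

* Continuous covariates are **independent** truncated normals per group.
  Only means ± SD are configured; inter-covariate correlation is *not*
  emulated (a correlation-matrix hook is the natural extension point).
  Consequences: collinearity diagnostics on synthetic cohorts are benign
  by construction (VIF ≈ 1), and passing tests say nothing about
  correlated-covariate behaviour on real data.
* Truncation (VCDR ∈ [0,1]; IOP, DD, BP, age > 0) is by **resampling**,
  not clipping, to avoid point masses at the bounds. With the default
  parameters the bounds are many SDs from the means, so truncation is
  numerically invisible.
* The seven SNPs are simulated **independently**: linkage disequilibrium
  between the three 9p21 SNPs is not modelled. Joint-genotype statistics
  across loci are therefore not meaningful in synthetic data.
* Genotype missingness is off by default (`missing_rate=0`); when enabled
  it is completely at random per SNP.
* No visit structure or loss to follow-up is simulated; "incident" is a
  single binary outcome over the whole follow-up window.

**Intercept calibration.** The shipped model constant (−16.221) was fitted
on real data whose covariate joint distribution differs from the synthetic
marginals, so using it verbatim gives far too few cases (mean linear
predictor ≈ −8.5 at population means). `calibrate_intercept` solves
mean<sub>i</sub> expit(c + η<sub>i</sub>) = target over a seeded 200 000-subject
population draw by Brent root finding (tolerance 10⁻⁶ on c; mean incidence
reproduces the target to ~10⁻⁴). Mean probability is strictly increasing
in c, so the root is unique. With the default betas the calibrated
intercept is ≈ −11.68.

Units: age in years, IOP/SBP/DBP in mm Hg, VCDR a proportion in [0,1], DD
in mm; coefficients are per unit of these scales and per risk-allele copy
for SNPs; sex is coded female = 1. The VCDR coefficient (0.827 per unit) is
used exactly as configured even though its magnitude suggests the original
fit may have used a 0.1-unit scale; the generator's truth is whatever the
configuration states.

## Association testing

* **Allelic test**: each genotyped subject contributes two alleles;
  missing genotypes are excluded. OR is the 2×2 cross-product ratio, the
  95% CI uses Woolf's log-OR variance (1/a + 1/b + 1/c + 1/d), and the
  p-value is the Pearson 1-df chi-square **without** continuity correction
  (the convention of standard GWAS toolkits). A zero cell raises a
  degenerate-table error rather than silently adding 0.5. Note the exact
  CI/p duality ("CI excludes 1 ⇔ p < 0.05") holds between the Woolf CI and
  the Wald p implied by β/SE, not the Pearson p; near-threshold tables can
  disagree slightly between the two.
* **Adjusted and joint models**: maximum-likelihood logistic regression
  (statsmodels), complete-case only (no imputation), genotypes as 0/1/2
  dosages oriented to the risk allele; Wald SE/CI/p per term.
  Non-convergence (e.g. separation) raises a diagnostic error.
* **Collinearity**: per predictor, OLS R² on the remaining predictors;
  tolerance = 1 − R², VIF = 1/tolerance; exact dependence reports VIF = ∞.
* **Multiple testing**: fixed Bonferroni over the number of SNPs tested
  (default 7 → threshold .007 at family α = 0.05), not per locus.
* **Baseline table**: Welch two-sample t (continuous), Pearson chi-square
  (sex); zero-variance variables get a missing p.

## Power

The case-control power computation follows the classic genetic-power-
calculator recipe: penetrances (f₀, f₁, f₂) solved by 1-d root finding so
that odds(f_g) = OR_g·odds(f₀) and the HWE-weighted mean equals the
prevalence; case/control genotype distributions by Bayes inversion
(controls screened disease-free by default; an unselected-controls flag
exists); noncentrality = the Cochran–Armitage trend statistic (scores
0,1,2) evaluated at expected counts; power from the noncentral chi-square.

The "additive model" for a per-allele OR is **odds-multiplicative**
(or_hom = or_het²) by default, with a risk-additive alternative
(or_hom = 2·or_het − 1) behind a flag, since the two conventions differ
and neither is universal. For the default design (67 cases / 1919 screened
controls, freq 0.30, per-allele OR 1.6, prevalence 5.67%, α = .007) the
analytic power computes to 47.2%, and agrees with brute-force multinomial
simulation (10 000 replicates) to within Monte-Carlo error; the acceptance
script performs exactly this computation and cross-check.

## Subset-ensemble importance ranking

* **Procedure**: for every non-empty subset of the variable panel
  (2^k − 1; 16 383 at k = 14) and every repetition, a fresh balanced cohort
  (all cases + an equal number of controls), a fresh stratified 70/15/15
  split, training with early stopping on the validation part, and the
  test-part error score (fraction misclassified at probability 0.5).
* **Network**: one hidden layer of 5 logistic units and a logistic output,
  trained by full-batch gradient descent with momentum (learning rate 0.5,
  momentum 0.9, ≤ 200 epochs, patience 10 validation evaluations,
  best-weights restore). The training loop is implemented directly in
  numpy because the procedure requires early stopping against a
  caller-designated validation set, and because at 134-row scale a
  full-batch numpy loop is orders of magnitude faster per run than a
  general-purpose SGD stack — the full 16 383 × 20 sweep is then a
  long-running but feasible single-CPU mode, and the reduced sweeps used
  in routine validation take seconds. Continuous inputs are standardized
  with training-set statistics; 0/1/2-coded inputs (sex, dosages) enter
  unscaled. Architecture and optimizer settings are constructor knobs.
* **Repetitions**: "trained and tested R times" is interpreted as R
  independent (control-sample, split, initialization) repetitions per
  subset — the control sample is redrawn every repetition to average over
  control-selection noise. Per-run seeds derive deterministically from
  (master_seed, subset bitmask, repetition) via `SeedSequence` spawn keys,
  so any single run is reproducible in isolation and reruns are exact.
* **Age matching**: greedy nearest-age matching without replacement,
  case order randomized by seed, |Δage| ≤ 2 years required, nearest-age
  ties broken toward the younger control; infeasibility raises an error
  naming the unmatched case ages.
* **Contribution estimator**: error scores are averaged over repetitions
  per subset, then paired differences error(S) − error(S ∪ {v}) are
  averaged over all 2^(k−1) − 1 subsets S omitting v. The paired form has
  lower variance than the marginal difference-of-means (which is provided
  as an alternative estimator). Ranks sort contributions descending; ties
  break by panel order. In subset-capped reduced runs, variables without
  any usable pair get a NaN contribution and sort last.
* **Reduced scale**: routine validation uses k ≤ 6 panels with 2–3
  repetitions and/or subset caps; the importance-recovery properties
  (planted signal ranks first; pure-noise contributions ≤ 0 in
  expectation) are checked over 20 master seeds at that scale. The full
  k = 14 × 20-repetition sweep is exercised only as an explicit
  long-running mode (`oagsim nn-rank`, checkpointable and resumable).

## Problem sizes used in validation

Coefficient recovery uses one prospective cohort of n = 50 000 (every
joint-model coefficient within 2 SE of its generating value); type-I error
uses 500 null replicates of n = 2000 (binomial 2-SE band around 5%);
analytic-vs-empirical power uses 10 000 simulated trend tests; calibration
checks use 200 000 draws; ensemble properties use 63-subset panels × 3
repetitions × 20 seeds. These sizes were chosen so each check's
Monte-Carlo error is small relative to its assertion band.

## Known limitations

* Independent covariates and independent SNPs (no LD, no covariance): the
  synthetic cohort cannot exhibit confounding between predictors, so
  adjusted and unadjusted estimates coincide in expectation.
* The logistic incidence model is the generator's truth; model
  misspecification (non-additive genetic effects, interactions,
  non-linearity in age) is out of scope.
* The error score weights false positives and false negatives equally on
  balanced samples; no calibration or AUC-style measure is computed.
* Importance contributions are procedure-specific (network size, early
  stopping, balanced resampling all enter); they are comparable within a
  run, not across differently configured runs.
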