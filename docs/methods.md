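# Methods

This note documents the statistical procedures implemented in `hfscore`,
the defaults chosen where the design was genuinely open, and what the
synthetic-data experiments can and cannot show.

## Cohort model and splitting

A cohort is a patient-level table validated against a schema of typed
variables (continuous or binary; candidate, outcome, id or auxiliary
roles). The one-year mortality outcome must be fully observed; covariates
may be missing (`NaN`, read from empty or `NA` CSV cells).

The derivation/test split emulates allocation by a random-number table: a
seeded uniform permutation assigns ⌈n/2⌉ rows to the derivation sample and
the rest to the test sample. A Bernoulli(½) coin flip per patient was
rejected because it cannot guarantee the near-balanced group sizes such
allocations produce. The seed is a required input; the same seed always
yields the same split.

Baseline comparability is assessed with the unpaired Student t-test
(continuous) and the Pearson chi-square without continuity correction
(binary; the large-sample convention). A variable constant in both groups
is reported with an undefined p-value rather than an arbitrary one.

## Missing data

Missing continuous covariates are handled by the dummy-indicator method:
a 0/1 was-missing indicator column is appended and missing cells are
replaced by the median of the observed values, keeping every patient in
the analysis. This is unbiased only under MCAR and is less efficient than
multiple imputation, which is deliberately out of scope. Binary
candidates are not imputed this way (the method is defined for continuous
variables); passing one is an error.

Indicator columns accompany their parent variable into the selection
models, but an indicator whose prevalence is at or below the 1% screening
floor is excluded from the bootstrap models: a near-empty indicator
quasi-separates in a large fraction of resamples and would only inflate
the discard count. The final selected model uses the risk factors only.

## Screening

Candidates are screened before modelling:

* binary candidates must exceed a prevalence floor (default 1%) — rare
  flags cannot be estimated stably and are disqualified regardless of
  significance;
* the remaining candidates qualify when their bivariate Spearman rank
  correlation with the outcome is significant at α = 0.05 two-sided
  (t-approximation for n > 10, exact permutation enumeration below), or
  when they are forced in on clinical-judgment grounds (a configurable
  list; nothing is forced by default).

## Bootstrap posterior-probability selection

The selection engine draws, per iteration, a nonparametric bootstrap
resample (n rows with replacement) of the derivation sample and refits
the full multivariable logistic model on all screened candidates jointly.
For each candidate it records whether the Wald 95% CI for its odds ratio
excludes 1; the posterior selection probability is the fraction of
completed iterations in which it does, and candidates at or above 0.9
(default; 10,000 iterations by default) are selected.

Although this family of procedures is sometimes advertised as "Markov
chain Monte Carlo simulation" in the clinical-score literature, there are
no priors, proposals or chains: it is a frequentist case-resampling
bootstrap with CI-exclusion counting, and it is implemented (and named)
as such.

Two probabilities are reported per candidate: the two-sided exclusion
probability used for selection, and the one-sided probability that the
candidate *increases* risk (CI excluded 1 on the harmful side). A strongly
protective factor therefore shows a harmful-direction probability near 0
while its two-sided probability drives selection — this is how protective
factors (e.g. female sex, higher BMI) enter the score with negative
weights.

Iterations whose refit fails — a single-class resample, diverging
coefficients (|β| > 15, the separation flag), a singular information
matrix, or no Newton convergence in 100 iterations at tolerance 1e-8 —
are **discarded and counted**, and the probability denominator is the
number of completed iterations. Discarding is the only defensible choice:
those resamples have no maximum-likelihood estimate to interrogate. If
fewer than half the iterations complete the run aborts, since that
signals pathological data (typically a rare covariate with too few
events) rather than sampling noise. Discard counts are surfaced in the
results and the pipeline manifest.

A calibration fact worth knowing when reading selection output: for a
truly null candidate the *expected* CI-exclusion fraction is not the
nominal 5%. The full-data Wald statistic is approximately N(0,1) under
the null and the bootstrap statistic is approximately N(z,1) given the
data, so the unconditional exclusion probability is
P(|N(0,√2)| > 1.96) ≈ 0.166, and in any single dataset a null candidate
that drew a chance association can sit far higher. The 0.9 threshold is
what makes the procedure conservative; the test suite checks both the
replicate-averaged rate against this closed form and that nulls never
reach the threshold.

## Logistic regression and standardized coefficients

Model fitting is ordinary maximum likelihood (Newton–Raphson via
statsmodels, parameter tolerance 1e-8, 100 iterations max). Inference is
Wald: OR = exp(β), 95% CI = exp(β ± 1.96·SE) with 1.96 used exactly.
Rank-deficient designs are rejected rather than silently repaired, and
separation is flagged as non-convergence rather than returning the
meaningless huge estimates.

Standardized coefficients use the logistic-distribution convention

    SC_i = β_i · SD(x_i) / (π/√3),

with SD the sample standard deviation of the predictor in the fitting
table. This is the convention of SAS PROC LOGISTIC's "standardized
estimate", and it is the convention under which the reference score's
printed standardized coefficients are recovered from its printed odds
ratios and covariate SDs (e.g. β = ln 4.2 with prevalence 0.426 gives
SC = 0.391; plain β·SD does not reproduce the printed 0.3886). SC is
invariant to affine rescaling of the predictor.

## Score construction

From the selected model's SCs:

1. initial weight `w_i = |SC_i| / Σ|SC|` (weights sum to 1; the sign of
   SC is carried separately so protective factors subtract);
2. non-age weights are multiplied by 100 and rounded to the nearest
   multiple of 5, with an exact half-grid tie (…2.5) rounded **toward
   zero** — the only tie rule consistent with the reference mapping of
   32.5 to 30; age is multiplied by 10 only and floored to one decimal
   (age spans ~20–90 years, so its per-year weight lives on a finer
   grid);
3. score = 100 + Σ sign_i·w*_i·x_i. The base 100 keeps typical profiles
   positive but scores are *not* clipped: a young low-risk profile can
   legitimately fall below 100 (the reference cohort's observed minimum,
   89.9, is itself below the base).

Tie behavior is configurable to round-half-up, but that departs from the
reference mapping and is off by default. Tiers partition the line at
300 and 800: low < 300 ≤ moderate ≤ 800 < high, both cut-points inclusive
to moderate.

The published fixed-weight score (1.5/y age, −15 female, +20/mm left
atrium, −20/unit BMI, +30 NYHA>3, base 100) ships as
`published_score_spec()` and can be applied to any cohort without
refitting. One caveat for users comparing against the reference worked
example: direct arithmetic for a 45-year-old woman with LA 30 mm, BMI 23
and NYHA ≤ 3 gives 292.5; the reference text prints 322.5 for that
profile, which corresponds to NYHA > 3 = 1 and is internally inconsistent
with the stated NYHA class 2. The implementation follows the formula.

## Evaluation

* **AUC** — the Mann–Whitney pairwise estimator (ties count ½), computed
  from average ranks in O(n log n); verified against O(n²) pair counting.
* **Max-rescaled R²** — Cox–Snell `1 − exp(2(L0−L1)/n)` divided by its
  maximum `1 − exp(2L0/n)`.
* **Hosmer–Lemeshow** — equal-frequency groups (default 10, the common
  software default; fixed-width binning is not offered) on the predicted
  probabilities, tied predictions kept in one group, df = groups − 2.
  Groups with a degenerate expected count are merged into a neighbour
  with a warning, df adjusted.
* **Two validation models** per evaluated sample, mirroring standard
  score-validation practice: the multivariable model on the selected risk
  factors, and a univariable logistic refit on the integer score; both
  are refitted on the sample being evaluated.
* **Tier mortality** — n, deaths and rate per low/moderate/high tier;
  empty tiers report an undefined rate.

## Synthetic cohort generator

The generator is the package's stand-in for the original (undeposited)
hospital cohort and defines the conditions under which everything is
tested:

* continuous covariates from the published normals — age 57.1 ± 12.4 y
  (rejection-sampled to the ≥20 y eligibility floor; negligible mass),
  BMI 25.1 ± 3.4 kg/m², left-atrial diameter 39.9 ± 7.9 mm, heart rate
  73 ± 14 bpm;
* binary covariates at the published prevalences (female 0.199,
  NYHA>3 0.427, LVEF<40 0.355, HF history 0.181, AMI 0.226, CHD 0.712,
  diabetes 0.278, hypertension 0.636, valve surgery 0.061, smoking 0.578,
  alcohol 0.351);
* outcome Bernoulli(expit(β₀ + Σβx)) with the published effect sizes on
  the five score variables and zero effect elsewhere; β₀ calibrated by
  bisection on a 200,000-draw Monte-Carlo mean to hit the 6.5% marginal
  mortality (tolerance 5e-4);
* MCAR missingness on covariates only (left atrium 3.8%, heart rate
  0.7%, age 0.2%), applied after the outcome is drawn.

Covariates are **mutually independent** by default because only marginals
were published. A Gaussian-copula correlation hook exists for sensitivity
analyses but defaults to the identity. Two documented consequences of
independence:

* the five-variable model's AUC on synthetic data is ≈ 0.76, a few points
  below the ≈ 0.79 reported on the real cohort, whose covariate
  correlations are unknowable from the published marginals;
* the synthetic score distribution is near-Gaussian (mean ≈ 491.5 by the
  analytic moment identity, SD ≈ 174) and does not reproduce the
  right-skewed tier occupancy of the real cohort (11.7 / 73.8 / 14.5%),
  so tier proportions are checked only qualitatively.

Passing tests on synthetic data therefore demonstrate correctness of the
*procedures* (selection operating characteristics, weight arithmetic,
calibration of the generator itself), not fidelity of any joint
distribution to the real patients.

## Problem sizes and numerical choices

The test suite runs the selection engine at 100–500 bootstrap iterations
on cohorts of 1,500–2,000 and law-of-large-numbers checks at n = 50,000;
the acceptance script uses 1,000 iterations at n = 2,000 and n = 50,000
cohorts for the distributional checks. These sizes put Monte-Carlo error
comfortably inside the asserted tolerances while keeping a full run in
well under a minute; production derivations default to 10,000 iterations.

Other numerical details: intercept calibration bisects on [−40, 15];
half-grid ties are detected with a 1e-9 tolerance so binary-float
representations of values like 0.325 are treated as exact ties; split
halves differ by at most one row for odd n (extra row to derivation);
seeded `numpy.random.default_rng` everywhere, with the pipeline keeping
separate seeds for generation, splitting and bootstrap so stages can be
varied independently.

## Known limitations

* No survival-time modelling — the outcome is a binary one-year flag.
* No repeated admissions, multi-centre stratification or covariate drift.
* MCAR-only missingness; no MAR/MNAR mechanisms, no multiple imputation.
* No penalized (e.g. Firth) regression: cohorts whose resamples separate
  in more than half the iterations abort by design.
* No confidence intervals on AUC and no decision-curve analysis.
* Tier thresholds are fixed at 300/800; no recalibration to external
  cohorts.
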