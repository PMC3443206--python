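# Methods

## Model and estimand

The analysis targets, for each of three binary disability outcomes and a
set *K* of *k* chronic-condition groups, the average attributable fraction
(AAF) of each condition: the expected additional fraction of disability
cases prevented by eliminating the condition after a random subset of the
other conditions has already been eliminated. Formally, with `AF(S)` the
joint attributable fraction of eliminating the subset *S*, the AAF of
condition *i* is the Shapley value of the set function `AF`:

    AAF_i = Σ_{S ⊆ K∖{i}} |S|!(k−|S|−1)!/k! · (AF(S∪{i}) − AF(S)).

Two exact properties follow and are enforced to numerical tolerance in the
test suite: *efficiency* (Σ AAF_i = AF(K), so the AAFs of all conditions
sum to the fraction of disability attributable to chronic conditions as a
whole, never above 100% when AF(K) ≤ 1) and the *dummy* property (a
condition whose model coefficient is zero receives AAF exactly 0).

`AF(S)` comes from model-based standardization (g-computation) on a single
survey-weighted logistic regression of the outcome on all *k* condition
indicators plus adjustment covariates:

    AF(S) = 1 − Σ_j w_j p̂_j(S→0) / Σ_j w_j p̂_j ,

where `p̂_j` is respondent *j*'s fitted probability at the observed data
and `p̂_j(S→0)` the fitted probability with every condition in *S* set to
zero. Assumptions: the logistic model is an adequate description of the
joint condition–covariate–outcome surface (all subset AFs inherit its
functional form); conditions act through their indicator main effects
(interactions can be added as covariates but are not part of the default
surface); weights render the respondent sample representative.

Design choices, made where the construction was genuinely open:

* **One jointly fitted model, not per-subset refits.** All 2^k subset AFs
  are evaluated from the same fit, which makes the subset lattice
  internally consistent and the efficiency identity exact to machine
  precision, and reduces each subset to one vectorised `expit` call
  (zeroing a condition only subtracts its linear contribution).
* **Predicted-case denominator.** Using Σ w p̂ rather than Σ w y in the
  denominator makes AF(∅) = 0 exact under any model misfit; an
  observed-denominator mode exists behind a flag.
* **Modes and caps.** Exact Shapley enumeration up to k = 12 (4096 memoized
  lattice entries); a permutation brute force (k ≤ 8) kept solely as an
  independent oracle; a Monte Carlo mode over sampled elimination orders
  for larger k, reporting per-condition Monte Carlo standard errors and
  reproducible by seed.
* **No confidence intervals for AAFs** are claimed; a design-respecting
  bootstrap could be layered on top but is not part of the core method.
* **Age-stratified runs refit the model within each age class; pooled runs
  add age class as an adjustment covariate.**

## Gross attributable fractions and grouping

Per condition, the gross AF uses Levin's formula `Pe(RR−1)/(1+Pe(RR−1))`
with the survey-weighted prevalence `Pe` and the *crude* weighted risk
ratio `RR` (Levin's formula presumes the population risk ratio; adjustment
belongs to the AAF stage). Conditions whose gross AF is ≤ 15% (ties
included) in every age class are merged into a single "other diseases"
indicator (logical OR) before the AAF analysis; the merged list is the
union across age classes so one factor set is used everywhere (a
per-age-class mode exists behind a flag). The threshold is a convention for
keeping the factor set interpretable, not a statistical criterion.

Confidence intervals for the gross AF are symmetric on the log(1−AF)
scale with the exact delta-method variance under multinomial
(cross-sectional) sampling of the 2×2 table,

    Var[ln(1−AF)] = a/(a+c)² + c(1/c − 1/(c+d) − 1/(a+c))² + d/(c+d)² − 1/n,

validated against a 10,000-replicate multinomial bootstrap in the test
suite. Weighted cell totals are rescaled to the Kish effective sample size
`(Σw)²/Σw²` before the variance is evaluated, since the count formula
presumes unweighted observations; this is a first-order correction, not a
full design-based variance.

## Weight chain

1. **Design weights** — inverse stratum sampling fractions
   (Horvitz–Thompson).
2. **Non-response adjustment** — a logistic response-propensity model fit
   on the full selected sample; respondent weights divided by fitted
   propensity; non-respondents then dropped (respondent-only analysis
   table). Propensities are floored at 0.02 (logged when applied) to cap
   weight inflation.
3. **Calibration** — multiplicative raking (iterative proportional
   fitting) to categorical margins, default tolerance 1e-8 on the maximum
   relative margin error, max 100 iterations, error on non-convergence or
   on an empty sample cell with positive margin. Raking preserves the
   weighted interaction structure (odds ratios) of the starting weights on
   the margin variables.

Variances of weighted means use Taylor linearization treating units as
sampled with replacement within strata — a deliberate, documented choice;
replicate-weight systems are out of scope.

## Outcome and exposure definitions

Disability derives from six ADL items (bathing, dressing, toileting,
transferring, preparing a meal, self-feeding), each scored 0 (no
difficulty) to 4 (inability to do it alone): *disabled* = any item ≥ 1,
*severely disabled* = any item = 4 (so severe ⇒ disabled structurally),
*self-reported* = affirmative answer to a direct question. Missing items
are an error by default; an available-case mode treats them as 0 with a
logged count. Transferring is one item covering bed and chair.

Condition groups are 12 ICD-10 groups over a 52-disorder checklist shipped
as an editable CSV resource (`code, label, group, symptom_exempt,
treatment_rule_applies`). A disorder counts only if physician-diagnosed
(symptom items — back pain, neck pain, headache — and the
question-derived sensorial items are exempt), treated during the previous
year (where the rule applies; the per-code applicability is a mapping-table
column, defaulting to all non-symptom codes), and not a stroke without
sequelae. Obesity enters the endocrine group as BMI ≥ 30 from height and
weight; with missing anthropometry and no other qualifying endocrine
disorder the endocrine flag is returned as unknown rather than false.

## Synthetic-data generator

The generator emulates the structure the analysis assumes, with known
ground truth:

* **Covariates**: age ~ 18 + 80·Beta(1.9, 3.1) (mean ≈ 48.4 y), sex,
  marital status, education, residence categorical; living-alone
  probability increasing in age.
* **Co-morbidity**: one shared standard-normal latent frailty per person;
  condition *j* is indicated when `λ_j·z + ε_j` exceeds the threshold
  matching its marginal prevalence. Pairwise association increases with
  the product of loadings while marginal prevalences stay exact. This is
  the simplest structure reproducing condition clustering; richer copulas
  are out of scope.
* **Outcomes**: logistic models (intercept + condition log-odds +
  covariate log-odds) per outcome. One shared uniform draw drives the two
  ADL outcomes (comonotone coupling) and severe ⇒ disabled is enforced by
  construction; the default spec gives the severe model the same slopes
  with a lower intercept, so both marginals stay exactly logistic and the
  oracle stays closed-form. Default prevalences and intercepts were set
  to emulate a large national household survey: condition prevalences
  between 1.9% and 65.4%, roughly 4% ADL-restricted, 1.4% severe, 12–14%
  self-reported, response rate 76.6%.
* **ADL items**: disabled persons receive item scores from a latent
  severity plus item noise (thresholded to 0–3), with at least one
  restriction enforced; severe persons get their worst item set to 4.
  Classifying the generated items reproduces the generated outcome flags
  exactly (tested).
* **Presumed severity** (filter-survey analogue, a generator convention):
  level 4 = any item = 4; level 3 = any restriction; level 2 = self-report
  only; level 1 otherwise.
* **Design**: strata = 4 presumed-severity levels × geographic areas
  (default 11); Bernoulli sampling within stratum (simplest unbiased HT
  weights; a fixed-size mode exists) with severity fractions
  0.08/0.25/0.50/0.90 — severe strata heavily oversampled, making the
  sampling informative for disability. Per-area multipliers default to
  uniform.
* **Non-response**: logistic in covariates and presumed severity; the
  intercept is root-found on the sample so the marginal response
  propensity hits a target rate (default 0.766).
* **Seeds**: one master seed; per-stage child generators derived
  deterministically (SeedSequence), so outputs are byte-identical per
  seed.

`true_aaf_oracle` computes ground-truth AAFs by g-computation with the
*true* model probabilities on the generated population and exact Shapley
combination — the estimand the survey analysis must recover.

**Age classes** are 18–40 / 40–65 / >65 with half-open boundaries
[18,40), [40,65), [65,∞); a switch moves exact age 40 into the young class
for the inclusive convention.

**What the generator does not emulate**: institutional (non-household)
populations, proxy-respondent measurement error, item non-response,
multi-stage household clustering, and age-dependent condition prevalence
(conditions are drawn independently of covariates). Passing recovery tests
therefore show correctness of the estimator under the stated design and a
correctly specified outcome model, not robustness to misspecification of
real survey data.

## Parameter-recovery scenario

The documented recovery fixture uses five conditions with prevalences
0.25/0.20/0.15/0.10/0.10, loadings 0.5, and well-separated condition
log-odds 2.0/1.5/1.0/0.6/0.3 on a 120,000-person population (≈ 20,000
sampled, ≈ 16,000 respondents), chosen so the true AAF ranking is
unambiguous (true AAFs ≈ 0.38/0.21/0.10/0.04/0.02). Over 50 seeds the
survey-weighted analysis recovers the true rank order and weighted
prevalences are unbiased within Monte Carlo error, despite the informative
sampling and MAR non-response.

## Numerical choices and degenerate inputs

* Raking tolerance 1e-8 (relative), max 100 iterations; exact fixed point
  detected without iterating.
* Logistic fits via iteratively reweighted least squares (statsmodels GLM,
  binomial family, `var_weights`); non-convergence is an error; separation
  is flagged when any coefficient exceeds 30 in absolute value or a factor
  has no variation, naming the term.
* Zero cells in the 2×2 make RR or the CI undefined: errors by default,
  with an optional +0.5 continuity correction.
* AF(S) with no predicted cases is an error; AF(∅) = 0 by construction.
* Report tables print percentages to one decimal and keep raw values in
  `*_raw` columns; AAF sum rows default to sums of unrounded values
  (formatted afterwards), since sums of printed rounded entries can differ
  in the last digit; a `sum_of_rounded` mode is available.
* Expected prevented cases = AAF × weighted disabled count, reported raw
  and rounded to the nearest 10,000 by default.

## Problem sizes

The test suite and acceptance script use populations of 2,000–120,000
people, 50 recovery seeds, 200 sampling replicates for the
Horvitz–Thompson check, and 10,000 bootstrap replicates for the CI check —
sizes at which every Monte Carlo tolerance in the suite is comfortably
resolved on a single CPU.

## Known limitations

* AAF variance estimation is not provided (only Monte Carlo error of the
  permutation sampling, which ignores sampling variability of the fit).
* The Kish-effective-n CI for gross AFs is approximate under strong weight
  variation.
* Exact enumeration is exponential in k; beyond 12 factors only the Monte
  Carlo mode is supported.
* The crude RR feeding Levin's formula is intentionally unadjusted; a
  covariate-standardized RR option exists but the AAF stage is the
  adjusted analysis.
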