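# Methods

This note documents the models and procedures implemented in `scdpipe`,
the assumptions they make, the parameters that matter, and the design
choices taken where the design was genuinely open.

## Complaint data model

The questionnaire is nine yes/no items spanning five cognitive domains:
orientation (Q1), memory (Q2), visuoperception (Q3, face recognition),
executive functions (Q4), and language (Q5–Q9: word-finding, reading,
writing, language production, language comprehension). Items are coded
0/1 and the total (0–9) is their sum. Missing complaint items are never
imputed: the classification rules are defined on complete nine-item
vectors, so a subject with a missing item is excluded from
operationalization with a logged warning.

## The four operationalization approaches

A subject with zero complaints is a healthy control (HC) under every
approach; the approaches differ only in how they treat complainers.

**Clinical.** Endorsed items are collapsed to the set of affected
*domains*. Memory in the set → amnestic; one domain → single-domain. A
deliberate consequence of the domain granularity: several language items
together still count as a single domain (word-finding + reading →
`naSCD-sd`). Item-level granularity is available by passing a per-item
domain map.

**Psychometric.** The cutoff is the nearest-rank (type-1) 90th percentile
of the total-complaint distribution — the smallest observed total such
that at least 90 % of subjects fall at or below it. The reference
population defaults to the full sample including zero-complaint subjects
(configurable to complainers only): with a study-like distribution the
full-sample convention yields the cutoff 2, i.e. "two or more complaints".
Nearest-rank is used everywhere a percentile of an integer-valued variable
is needed, because it returns an attained integer value rather than an
interpolated one.

**Distribution.** Quartile cuts of the totals are computed by the same
nearest-rank rule (study-like data give 0 / 1 / 2, i.e. quartiles of 0, 1,
2 and 3+ complaints). Subtypes are exact complaint patterns: {memory} →
amnestic, {word-finding} → anomic, {memory, word-finding} → both, any
non-empty pattern sparing both → atypical; every other complainer is
non-SCD. The pattern definitions make subtype counts + non-SCD = number of
complainers an exact conservation law, which the tests enforce.

**Multivariate.** Two stages:

1. *Severity component.* PCA on the standardized cognitive battery plus
   four ADL measures (FAQ and the three BDRS subscales), five components
   by default. The clinical-severity component is the one on which **all**
   ADL variables attain their maximum absolute loading
   (correlation-scaled); if several qualify, the one with the largest
   summed absolute ADL loading wins; if none does, selection fails loudly
   rather than guessing. The component is sign-oriented so that lower
   scores mean worse clinical-cognitive status (ADL-burden loadings
   negative).
2. *Complaint selection.* A random-forest regression predicts the
   component score from the nine complaints plus age, sex (female = 1),
   crystallized intelligence (WAIS-III Information) and the harmonized
   depression z-score. Importance is **out-of-bag permutation
   importance**: for each tree, the increase in out-of-bag MSE when one
   predictor's column is permuted, averaged over trees — the classical
   "loss when a predictor is perturbed out of the model" convention.
   A complaint is selected when (a) its importance exceeds
   `max(importance_threshold, 0.10 × the largest complaint importance)`,
   (b) the importance is significantly positive (mean > 2 between-tree
   standard errors), and (c) its point-biserial correlation with the
   oriented component is negative (endorsement associated with worse
   status). The guards in (a) and (b) exist because permutation importance
   of a predictor that deep trees occasionally fit noise with is slightly
   positive *on average*; a strictly-positive cut therefore admits noise
   complaints. For the same reason the forest is regularized with
   `min_samples_leaf = 10`. All thresholds are configurable.

Subjects endorsing any selected complaint — alone or in combination —
form the multivariate SCD group.

## Depression harmonization, inclusion, imputation

Depressive symptomatology mixes two instruments: BDI below age 63, GDS at
63 and above. Each scale subgroup is z-scored against its own mean and
**sample** SD (n−1; the standard convention for z-scores on a study
sample, configurable) and the two z columns are concatenated. Inclusion
keeps subjects with BDRS total ≤ 4, FAQ ≤ 5 and MMSE ≥ 26 (inclusive
boundaries). Missing cognitive values (~2 % under the default generator)
are imputed by per-column median; stratified median (by decade of age) and
seeded iterative regression imputation are available. The order
(inclusion before imputation) is a configuration choice; the default
imputes on the included sample.

## The disease severity index

**Residualization.** Each sMRI feature is regressed on age (thickness
features) or age + intracranial volume (volumetric features) by OLS.
Coefficients are estimated on the healthy-control training subjects only —
fitting on cases too would absorb disease-correlated age variance into the
"nuisance" model — and applied to everyone, including unseen cohort
subjects.

**OPLS.** On unit-variance-scaled residualized features X and class
coding y (HC = 0, AD = 1), orthogonal components are peeled off one at a
time: the candidate predictive weight `w ∝ X'y` is computed, the loading
`p` of its score is split into the part collinear with `w` and the
remainder `w_orth`, and the variation along `w_orth` is deflated from X.
Scores of orthogonal components are exactly uncorrelated with y by
construction (enforced to 1e-10 in tests). After `k` such components a
single predictive component is fitted; with `k = 0` the model reduces
exactly to one-component single-response PLS, which the tests verify
against an independent NIPALS oracle. R²(X) is the fraction of scaled-X
variance captured by predictive plus orthogonal components; R²(Y) the
in-sample fraction of class variance explained.

**Cross-validation.** Q²(Y) = 1 − PRESS/SS over stratified sevenfold
held-out predictions, with all preprocessing (scaling, OPLS fit) nested
inside each training fold. Interpretation bands: > 0.1 acceptable, > 0.5
good, > 0.9 optimal. The number of orthogonal components defaults to the
sevenfold-Q² maximizer over 0–3 (explicit override supported); on the
default synthetic reference the maximizer is usually 0–1.

**Projection.** A new subject's residualized feature vector is scaled
with the *training* means/SDs, its orthogonal variation is removed with
the training orthogonal weights/loadings, and the predictive score is
mapped through the training regression onto the 0–1 class scale. No
clipping is applied: values slightly outside [0, 1] are legitimate (a
very control-like subject can score below 0). Closed-form anchor: the
training grand-mean vector projects exactly to the case fraction
n_AD/(n_HC+n_AD) — 39/108 ≈ 0.361 for the default 69/39 reference.
Region contributions are ranked by |predictive weight| (ties broken
lexicographically); a negative sign means the feature is reduced in
cases, so ventricular features carry positive signs. AD-like
dichotomization uses the nearest-rank 90th percentile of the projected
cohort (HC-only reference optional), flagging scores **at or above** the
threshold.

## Characterization suite

* Random-forest classification of each SCD group against HC over
  demographic, clinical and cognitive predictors, reporting per-class
  out-of-bag error against the error-by-chance of a uniform guesser,
  100·(1 − 1/k) for k classes. A model is only informative if it beats
  that rate; with groups defined purely by complaints, it should not.
* Random-forest regressions of the severity index and of white-matter
  signal-abnormality (WMSA) volume on the complaints plus covariates; age
  and ICV enter only the WMSA model, because the severity index is
  already adjusted for both during its creation.
* Borderline performance: component scores are residualized on age, sex
  and crystallized intelligence over the reference population; the
  nearest-rank 10th percentile of reference residuals is the threshold,
  and the report gives the percentage of each group at or below it
  (≈10 % of the reference by construction).
* Subtype-size contrasts use the two-cell equal-proportion goodness-of-fit
  χ² = (a−b)²/(a+b) on 1 df, without continuity correction. The
  alternative contingency-table reading was rejected because it does not
  reproduce the reference contrast values the package validates against;
  this form reproduces all seven to two decimals.
* Omnibus group contrasts: ANOVA / ANCOVA (OLS with covariates;
  Kruskal–Wallis and Mann–Whitney for nonparametric routing; χ² for
  categorical variables), with pairwise post-hocs Hochberg-adjusted
  (step-up, monotone, capped at 1). Partial correlation is the Pearson
  correlation of OLS residuals, with the t-test on n − k − 2 df.

## Synthetic data generator

The generator emulates a community-based ageing cohort screened for
normal functional status. Five independent standard-normal latent factors
(visual, verbal memory, visual memory, clinical severity,
executive/premotor) drive a configurable cognitive battery (default 20
variables, up to 67; primary loadings 0.7, unit-variance targets), with
alternating verbal-memory variables cross-loading 0.45 on severity — the
episodic-memory/fluency mixing that makes them cluster with the ADL
measures in the PCA. ADL scales are discretized monotone transforms of
the inverse severity factor, bounded at 0 and hence floor-heavy
(> 50 % zeros). Complaints are Bernoulli draws through a logistic link on
the factors; each item's intercept is solved numerically (Gauss–Hermite
quadrature + Brent root finding) so its marginal prevalence hits the
target exactly regardless of the dependence structure. Defaults:
word-finding 0.36, memory 0.27, other items 0.04–0.07, with an amnestic
cluster (orientation/memory ← verbal memory + severity) and an anomic
cluster (word-finding/language ← executive, word-finding also on verbal
memory, writing/production/comprehension also on severity). Link
magnitudes were sized so the totals distribution has the quartile
structure such cohorts show (≈42 % zeros at scale; quartiles 0 / 1 / 2 /
3+; 90th percentile = 2). Because the true distribution sits close to
both quartile boundaries, individual n≈400 draws can flip a cut by one —
structure checks therefore run at n = 5000.

The sMRI reference generator draws a 69 HC / 39 AD panel (configurable)
over 68 cortical-thickness and 21 subcortical-volume features with
FreeSurfer-style names. AD shifts are expressed in units of the
within-group residual SD (net of age/ICV variance): hippocampus −1.8
bilaterally (the dominant effect), inferior lateral ventricles +1.2,
entorhinal/precuneus −1.0, supramarginal (right −0.9, left −0.5),
inferior parietal −0.9, plus a mild −0.3 global thinning. Age slopes and
an ICV proportionality affect all subjects through one shared law, so
residualization can remove them for reference and cohort alike.
`attach_smri_to_cohort` gives cohort subjects the same feature panel with
the atrophy pattern scaled by `severity_link × (−severity factor)`
(default 0.15, chosen so the projected index distribution has an HC-like
mean near 0, SD ≈ 0.2 and a 90th percentile near 0.3) and WMSA growing
with age and the inverse executive (anomic) factor.

What the generator does *not* emulate: item-level test responses,
measurement non-normality and practice effects, correlated latent factors
(an option exists but the default is orthogonal, matching the PCA's
orthogonal components), site/scanner effects, and genuinely informative
missingness (injection is MCAR). Passing tests therefore demonstrate the
correctness and calibration of the pipeline under its stated model, not
robustness to those real-data complications.

## Problem sizes and runtimes

The API default for random forests is 5000 trees; the test-suite and the
acceptance script use 100–500 trees and cohorts of 300–5000 subjects,
sizes at which every statistic involved has comfortably converged for the
checks being made (the planted-rule recovery rate, for example, changes
by < 5 points between 300 and 5000 trees). The full suite runs in about a
minute on one CPU.

## Known limitations

* The OPLS implementation is the single-response form; multi-class
  extensions are out of scope.
* Q²'s denominator uses the total sum of squares around the overall class
  mean; other software sometimes uses per-fold training means, which can
  differ in the third decimal at these sample sizes.
* The severity index is only identified up to the reference panel's
  composition: a different HC/AD mix moves the grand-mean anchor
  (n_AD/n total) and hence the whole scale.
* With an empty learned rule the multivariate approach labels every
  complainer non-SCD (logged), which is the honest degenerate output, not
  an error.
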