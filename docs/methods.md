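# Methods

This note documents the statistical machinery in `recoverlab`: the models
and estimators, the assumptions they make, the parameters that matter, what
the synthetic cohort generator does and does not emulate, and the places
where the design was genuinely open and a choice had to be made.

## The prediction problem

Patients with mild TBI (GCS 13–15) and a normal CT are dichotomized at
three months into complete recovery (GOSE = 8) and incomplete recovery
(GOSE < 8). Five published clinical models (UPFRONT-ED, UPFRONT-PLUS,
HeadSMART, CENTER-ED, CENTER-PLUS) are refitted to the cohort by maximum
likelihood — recalibration, not transport of published coefficients — and
the question is whether serum biomarkers (log GFAP, log S100B, log NFL) or
a DTI summary add discrimination and explained variation beyond them.
Variable codings are declared defaults: education as an ordered 1–3 score
(the UPFRONT age × education interaction multiplies the numeric scores),
injury mechanism categorical with a road-traffic reference, ASA physical
status 1–3. Neck pain, coping styles and pupil reactivity are not in the
cohort schema and are omitted; prior mental health substitutes for prior
depression; a positive-CT indicator would be constant in a CT-negative
cohort and is auto-pruned as degenerate.

## Synthetic cohort generator

The generator is the test bed for every stage; its defaults are the study
conditions: 1025 biomarker-cohort patients at 38% incomplete-recovery
prevalence (DTI sub-cohort analyses use n = 153 at 46%), 157 healthy
controls aged 21–68, 17 scanners, patient ages 20–70 with reference age 44.

Per tract t and metric (FA, MD), a subject's observed value is

    y = b0_t + b1_t (age − 44) + b2_t (age − 44)² + γ_s,t + δ_s ε,

with ε ~ N(0, σ²) the subject's true biological deviation (σ = 0.025 FA,
0.040 MD units of 10⁻³ mm²/s), γ_s,t an additive scanner-by-tract offset
(drawn N(0, 0.012) FA / N(0, 0.020) MD — each machine biases regions
differently, which is also the exchangeable structure the harmonization
prior assumes), and δ_s ∈ [0.75, 1.35] a multiplicative scanner noise
scale. FA baselines sit in 0.42–0.62 and decline ~8×10⁻⁴/yr; MD baselines
in 0.70–0.90 rise ~1.2×10⁻³/yr, both with mild curvature, matching the
magnitude of normal white-matter ageing.

The outcome is Bernoulli with log-odds = intercept + modest clinical terms
(symptom score, PTA, GCS, prior mental health, age, education, two-week
questionnaires — calibrated so the clinical models reach their realistic
AUC range of 0.6–0.7) + Σ β_j z(ε_j) over the configured effect tracts.
The default seeds effects of one log-odds unit per SD in three
tract-metrics (left superior cerebellar peduncle FA, right uncinate
fasciculus MD, left posterior thalamic radiation FA — the tracts reported
as most prognostic). The intercept is solved by root-finding so the
marginal prevalence matches the configuration exactly as n grows.

Biomarkers are log-normal given outcome group and sampling window
(<12 h vs 12–24 h post-injury), with locations anchored near the reported
triage cutoffs (e.g. GFAP ~0.10 vs ~0.20 ng/ml in the early window; NFL
rising into the late window). Missingness is missing-at-random given
observed age, GCS and education, with two-week questionnaires missing far
more often (~26%) than acute variables (~2–10%), so the imputation module
is exercised realistically; an off-by-default switch makes GOSE missingness
depend on the outcome itself for MNAR stress tests.

What the generator does *not* emulate: spatial correlation among
neighbouring tracts beyond the shared age trajectory, any dependence of
biomarker level on tract values given outcome (declared conditional
independence), biomarker assay floors/ceilings, scanner–site nesting, and
ordinal GOSE dynamics. Passing tests therefore show the estimators are
correct under the generator's assumptions, not that real data meet them.

## ComBat harmonization

Parametric empirical-Bayes location/scale adjustment per tract-metric
feature: standardize against a design of batch indicators plus covariates
(age, age², sex, time since injury, GCS, MR-abnormality — age² as a raw
squared term since only the column span matters here), estimate per-batch
location γ and scale δ² in standardized units, shrink them via
method-of-moments normal / inverse-gamma priors with the iterative
conditional posterior means, then adjust and restore the covariate fit.
The implementation agrees with the reference parametric ComBat to < 1e-6
on a frozen shared fixture (`tests/data/combat_fixture_*`).

Numerical choices: a single batch has no contrast, so γ* = 0, δ* = 1
exactly (identity adjustment); features with zero within-batch variance are
skipped with a warning (the scale posterior is undefined); constant
covariate columns (e.g. GCS in a healthy-control table) are dropped with a
warning, whereas genuine collinearity among non-constant columns is an
error naming the offending columns; unseen batch labels at apply time are
an error, never a silent pass-through.

Two honest limitations, measured on the generator: (i) when every feature
carries an identical batch shift, the exchangeable prior shrinks the
per-feature locations toward their common mean and a residual batch
difference of a few percent of an SD can remain — the prior is *designed*
for feature-varying effects; (ii) after adjustment, batch-mean differences
driven by covariate composition (older patients on one scanner) remain by
construction, because that variance is deliberately preserved. Tests
separate these effects by matching covariates across batches or
residualizing before comparing batch means.

## Age detrending

Healthy-control trajectories are fitted per tract-metric by OLS on a
centred-and-normalized quadratic basis u = (age − ā)/s, [1, u, u² − mean(u²)],
whose constants are stored with the model so out-of-sample prediction is
exact; predictions are identical to a raw-polynomial fit (orthogonality
only conditions the normal equations). A patient value f at age a becomes
f + [pred(44) − pred(a)]: the normal ageing difference is added, nothing
about the patient's own deviation is touched, so the map is affine in f
and exactly the identity at the reference age. Ages outside the control
fitting range are still corrected but returned in an extrapolation audit
list. Detrending runs after harmonization, and controls are harmonized
jointly with patients before trajectory fitting.

## Multiple imputation and pooling

Chained equations over all analysis variables: predictive mean matching
(Bayesian coefficient draw, five nearest donors on the predicted value)
for numeric variables — which keeps integers integer and positives
positive — and ridge-stabilized Bayesian logistic draws for binaries;
unordered string categoricals fall back to draws from their observed
distribution. Ten cycles, variables filled least-missing first, m = 10
completed datasets by default, observed cells bit-identical across them.
The derived outcome flag is always recomputed from imputed GOSE rather
than imputed itself. Estimates are pooled by Rubin's rules
(T = W + (1 + 1/m)B, large-sample df, Barnard–Rubin correction available
when a complete-data df is supplied), with AUC pooled on the logit scale,
calibration slope on the log scale (falling back to identity if a
corrected slope is non-positive), R² and proportions on the identity
scale. Outcome-missingness sensitivity uses best-case (all missing →
complete recovery) and worst-case (→ incomplete) bounds.

## DTI score

L1-penalized logistic regression over the 96 age-corrected, z-scored tract
metrics; standardization constants come from the fitting sample only and
are stored on the model. The penalty grid is 100 log-spaced values from
λ_max (the smallest penalty zeroing all slopes) down to 10⁻⁴ λ_max;
"10 × 10 cross-validation" is 10-fold CV repeated 10 times with
re-randomized folds; the retained λ minimizes mean held-out binomial
deviance (λ_min, the default prediction-error measure), with an
alternative that maximizes held-out concordance (`cv_measure="auc"`). The
final model is refitted on all rows at λ_min. The model's output is the
predicted odds of incomplete recovery; the *log*-odds (linear predictor)
is what enters downstream logistic models, being scale-stable in refits —
both are exposed.

The path solver is coordinate descent within penalized IRLS, warm-started
along the grid, with active-set iteration, glmnet-style scale-aware
convergence (max weighted squared coefficient change), fitted-probability
clamping at 10⁻⁵, a hard per-penalty sweep budget, and early path
termination once ~95% of the null deviance is explained — deep-overfit
penalties are never the CV winners, so their accuracy is irrelevant while
their cost is not. Against an unclamped reference solver the path agrees
to ~10⁻⁶ in the region CV selects from.

Selection frequency per tract-metric is the fraction of runs (bootstrap ×
imputation) with a nonzero coefficient; tables sort by the mean of the FA
and MD frequencies. A caveat established on the generator: at λ_min the
*number* of admitted noise predictors is intrinsically variable (roughly
3–15 extra columns at n = 400), and grows when effects are stronger
because CV then prefers smaller penalties; what is stable is that true
effect tracts are selected and carry the largest coefficients. Rank
stability of the top tracts needs cohorts of several hundred subjects —
within a single small dataset, chance correlations between noise tracts
and outcome are fixed features that repeat across bootstrap runs.

## Internal validation

Harrell's optimism bootstrap inside each imputed dataset: refit the entire
pipeline on each resample — including the lasso, when the model contains
the DTI score — score it on the resample and on the original data, and
subtract the mean gap from the full-sample apparent value. Resampling is
stratified on outcome by default (plain resampling by flag); single-class
resamples are redrawn and counted. Corrected metrics are pooled across
imputations by Rubin's rules; 95% intervals come from the percentiles of
the test-performance draws pooled over imputations. Classification metrics
use a predicted-probability threshold equal to the fitting sample's
outcome prevalence (configurable) — the prevalence threshold keeps
sensitivity and specificity away from degenerate corners.

Honest refitting of the lasso inside every resample is the default; the
cheaper variant that fixes the DTI score once is available by flag and is
demonstrably optimistic. Within resamples, the lasso's CV folds are
*grouped by original subject*: a bootstrap resample contains duplicate
rows, and letting copies of one subject sit on both sides of a CV split
leaks information, biases the penalty downward and inflates optimism. With
grouping, the honest loop corrects a 96-predictor pure-noise pipeline back
to a mean AUC of ~0.50 at n = 153.

Two measured limitations of the optimism bootstrap itself, reproduced here
with independently coded reference loops: (i) at small n with many noise
predictors but no selection (10 covariates, n = 60), the correction removes
only about two-thirds of the inflation (corrected ≈ 0.60 for a true 0.50) —
the estimator is consistent but biased at these ratios; (ii) for aggressive
selection procedures (concordance-maximizing CV at p ≈ n), bootstrap-test
performance on the original sample is inflated by the ~63% row overlap and
substantial residual optimism remains. Corrected values should be read as
upper bounds on honest performance in overfit-prone regimes. When the
deviance CV is applied to pure noise it frequently selects the empty model
outright, in which case apparent discrimination is exactly 0.5 and there
is nothing to correct.

Nested models (with vs without an add-on) are compared by the likelihood
ratio: classical χ² for a single dataset, Meng–Rubin D3 pooling across
imputations. The same CV partition seed is used for every imputed dataset
when constructing the DTI covariate: fold re-randomization would inject
pure Monte-Carlo noise into the between-imputation variance, which D3 then
(correctly, but uselessly) penalizes.

## Biomarker triage

Per biomarker and sampling window, candidate cutoffs are the midpoints of
sorted unique concentrations plus sentinels beyond both extremes; among
cutoffs with sensitivity ≥ the floor (default 0.90; sweep 1.00 / 0.95 /
0.90 / 0.80), the one with the highest specificity is returned, ties
breaking toward the higher cutoff (fewer scans). The convention is
concentration ≥ cutoff ⇒ scan (strict inequality by flag). Reported
sensitivity/specificity are apparent (resubstitution) values — this is an
exploratory analysis and is labelled as such. Avoided MRIs are the true
negatives, unnecessary MRIs the false positives, missed incomplete
recoveries the false negatives; display percentages are against the window
N with half-up rounding; number needed to scan is defined here as scans
performed per incomplete-recovery patient scanned, (TP+FP)/TP to one
decimal — a declared convention. An infeasible floor returns the minimum
concentration with a flag; a floor of zero is accepted but flagged
degenerate (it optimizes specificity alone). Windows with fewer than 10
subjects are flagged rather than suppressed.

## Problem sizes

Study-scale defaults (200 bootstrap × 10 imputations, 10×10-fold CV over
100 penalties) are used for one-off fits; the test suite and the
reproduction script scale the Monte-Carlo loops down (typically 50
resamples × 3 imputations, 4-fold CV over 20 penalties inside resamples,
cohorts of 120–1025) — sizes chosen so each check has adequate statistical
power for the property it asserts, and stated inline where they appear.

## Known limitations

- The generator's conditional independence of biomarkers and tract values
  given outcome means biomarker-triage and DTI-prognosis results cannot
  interact in simulation, unlike in patients.
- Optimism-corrected metrics inherit the estimator biases quantified
  above; external validation is out of scope by design.
- Non-parametric ComBat, longitudinal harmonization, site-level nesting,
  sex-specific or spline ageing trajectories, and ordinal-GOSE models are
  not implemented.
- The imputation engine covers the variable types present in the cohort
  schema; it is not a general mice replacement (no polytomous regression,
  no passive imputation).
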