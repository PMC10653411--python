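# Methods

This note records the statistical model, the numerical choices, and the
design decisions behind `svyequity`, together with what the synthetic-data
validation does and does not demonstrate.

## Estimands and estimation

All quantities are design-based estimates for a finite population surveyed
with a stratified multistage design: respondent *i* carries a sample weight
`w_i` (inverse inclusion probability, possibly adjusted), a design stratum
*h*, and a primary sampling unit (PSU) *j* within the stratum.

A subgroup's **target share** is the weighted proportion of subgroup members
among the target population (e.g. diabetic adults); its **observed share**
is the weighted proportion of subgroup members among target-population
members who received the service. Both are ratio estimators
`R = Σ w·y / Σ w·x` with domain indicators in numerator and denominator.

**Variance.** Ratio estimators are linearized: the influence value of row
*i* is `z_i = w_i (y_i − R x_i) / Σ w x`. Influences are summed to PSU
totals; within each stratum the between-PSU sum of squares about the
stratum mean, inflated by `n_h/(n_h − 1)`, is accumulated over strata. This
is the with-replacement first-stage ("ultimate cluster") approximation that
is standard practice for NHANES-type designs; finite-population corrections
are deliberately omitted (they are unavailable without frame counts and the
approximation errs conservative under without-replacement sampling). A
stratum containing a single PSU contributes its squared deviation from the
grand mean of PSU totals by default (`lonely_psu="center"`); an error mode
is available.

**Effective sample size.** Significance testing on weighted shares uses the
Kish effective n, `(Σw)² / Σw²`, computed over the relevant denominator
rows. It equals the raw n under equal weights and discounts unequal
weighting.

## The equity metric and its classification

For observed share `p_obs` and target share `p_tgt`, the score is the log
(natural) odds ratio `log[(p_obs/(1−p_obs)) / (p_tgt/(1−p_tgt))]`.
Thresholds derive from disparate-impact rule fractions via
`τ = −log(1 − τ_rule)`; defaults are `τ_rule = 0.2` (the classic 80% rule,
`τ_l ≈ 0.22314`) and `0.4` (`τ_u ≈ 0.51083`), both configurable, with
significance level `α = 0.05`.

Classification order:

1. an observed share of exactly zero with a positive target share is
   **Absent** (a `−inf` sentinel, not a continuity-corrected score; no
   continuity corrections are applied anywhere);
2. a cell whose observed/target gap is not significant (`p > α`) is
   **Adequate** regardless of score — the gate prevents large but noisy
   scores in small cells from being over-read;
3. otherwise the score is graded on half-open bands
   `(−∞,−τ_u) | [−τ_u,−τ_l) | [−τ_l,τ_l) | [τ_l,τ_u) | [τ_u,∞)`.

All printed category ranges in this package (PIR "1–1.9", HbA1c "6%–7%",
the threshold bands) are half-open `[lower, next_lower)` so that categories
partition the line; boundary membership is fixed by tests.

**The significance test** (default) is an exact binomial test of the
subgroup count among recipients against the target share, with trials set
to the rounded Kish effective n of the recipients — a design-adjusted
exact test. A normal-approximation mode using the linearized SEs of both
shares is provided (`method="normal"`); the choice between the two is a
genuine modelling degree of freedom and both are exposed. No
multiple-testing correction is applied across cells by default (a
Bonferroni option exists) since each cell is reported, not selected.

Cells where a subgroup level simply does not occur inside a conditioning
stratum are *structurally missing* — rendered uncolored, distinct from
Absent (which is an observed zero among a present subgroup).

## Survey-weighted logistic regression

The model maximizes the weighted Bernoulli log-likelihood by IRLS
(convergence: relative deviance change < 1e-8, cap 25 iterations;
separation is detected by diverging coefficients with fitted probabilities
pinned within 1e-10 of 0/1 and raised as an error naming the term).
Because weights are sampling weights rather than frequency weights, the
covariance is the linearization sandwich `H⁻¹ G H⁻¹`: `H` is the weighted
information `Xᵀ diag(w p(1−p)) X` and `G` aggregates the score
contributions `u_i = w_i (y_i − p_i) x_i` to PSU totals exactly as for
ratio estimators. Inference uses a t reference with the design degrees of
freedom `#PSUs − #strata`.

Categorical covariates are treatment-coded against declared reference
levels; *ordered* covariates (education, CCI level, HbA1c band) enter as
per-level indicators rather than scores, so each level gets its own odds
ratio against the lowest level. Age enters continuously for vaccination
models and as the three adult diabetic bands for drug models (both
configurable). Outlier diagnostics compute weighted standardized Pearson
residuals (weights normalized to mean 1, leverage-adjusted); rows beyond
the cutoff (default 3) are reported, never dropped.

Coefficients are invariant to uniform weight rescaling, and so are the
sandwich SEs (H scales linearly, G quadratically); a test pins this.

## Harmonization choices

- **Cycle combination** divides each weight by the number of combined
  2-year cycles, so combined weighted totals estimate the average
  population over the period (standard multi-cycle analytic practice).
- **Insurance**: respondents reporting several plans resolve by the
  priority private > Medicare > Medicaid > other non-private (private
  first, matching its use as the regression reference class; the order is
  configurable). "Uninsured" requires every plan flag to be explicitly
  negative; a respondent with no positive flag and any unanswered flag is
  missing.
- **Adult age cutoffs** are implemented as completed years, `age ≥ 20` by
  default with a strict-inequality switch, since survey age is
  integer-valued.
- **Missing-value codes** (refused/don't know) are declared per variable in
  the codebook YAML, never hard-coded.
- **Education** harmonizes fine-grained codes ("12th grade no diploma",
  "GED") onto five analysis levels through the codebook's group map.
- Rows with "other/unknown" race/ethnicity are retained as their own level
  by default (dropping them is a caller-side filter); the provenance log
  records every operation with row counts, which are checked to be
  non-increasing.

## Charlson Comorbidity Index (a reconstruction)

The survey instrument offers 15 self-reported conditions, not the full
Charlson item set, so the weight table here is a documented reconstruction
mapping those conditions onto original Charlson components: myocardial
infarction, congestive heart failure, stroke and liver disease weight 1;
kidney disease and cancer weight 2; asthma, emphysema, chronic bronchitis
and COPD collapse onto the single chronic-pulmonary component (weight 1,
counted once); hypertension, arthritis, gout and coronary heart disease are
not Charlson components and weight 0. Diabetes contributes 1, or 2 with
retinopathy (end-organ complication). Severity bands: 0 none, 1–2 mild,
3–4 moderate, ≥5 severe. The table ships as editable configuration.

The drug formulary is a representative ~50-product subset spanning all ten
therapeutic categories (nine single-ingredient classes plus combinations),
with combination products decomposable into ingredients; names match
case-insensitively after whitespace normalization. Completeness of any
real national formulary is out of scope.

## The synthetic generator

`Scenario` defaults define the study conditions: 15 strata × 8 frame PSUs ×
600 residents (72,000 census), of which each cycle draw samples 2 PSUs per
stratum × 150 respondents, three 2-year cycles ≈ 13,500 rows. Covariate
marginals are chosen to resemble the U.S. adult population at desk scale
(62/12/6/17/3% race distribution, log-normal income-to-poverty ratio capped
at 5, education 8/12/24/31/25%); HbA1c is a two-component mixture
(non-diabetic 5.4 ± 0.35%, diabetic 7.4 ± 1.4%) so glycemic conditioning
strata are populated; comorbidity prevalences are fixed per condition.
Outcomes are Bernoulli draws from logistic models with configurable true
odds ratios (defaults near the 0.9–1.2 range typical of vaccination
disparities) plus an optional per-subgroup odds multiplier that injects a
known disparity; a non-positive multiplier is rejected as infeasible.

Sampling is two-stage **with replacement at both stages** — PSUs uniformly
within stratum, respondents with probability proportional to a race-based
oversampling factor (1.6–1.8 for minority groups, mimicking survey
oversampling). The weight is the reciprocal of the per-draw expected number
of selections (Hansen–Hurwitz), making weighted totals exactly unbiased for
census totals and making the with-replacement variance estimator correctly
calibrated — which the repeated-sampling test verifies (mean SE within 10%
of the empirical SD over 2,000 draws). Mild PSU-level heterogeneity (a
random intercept, sd 0.15 logits, and an income location shift) produces a
genuine clustering effect.

What this does **not** emulate: the real survey's four-stage selection,
nonresponse and post-stratification adjustments, measurement error in
self-reported medication use, and realistic joint dependence among
covariates. Passing tests therefore demonstrate correctness of the
estimators and classification machinery under a known design — not fidelity
of any particular substantive estimate to the U.S. population.

## Validation sizes

The statistical acceptance checks run at: 2,000 replicates at effective
n = 1,000 for the type-I error of the gate (expected 5% ± 2%); 500
replicates at effective n = 5,000 per injected multiplier
{0.5, 0.75, 1.0, 1.35, 2.0} for band recovery (≥ 90% expected: the nearest
band edge is ≥ 1.8 null-SEs away at that size); 300 replicates at n = 8,000
(10 strata × 4 sampled PSUs × 200) for CI coverage (93–97% band); 2,000
replicate draws for SE calibration; and n = 12 against a derivative-free
direct maximizer of the weighted likelihood (agreement to 1e-6). These
sizes were chosen once as the smallest that keep Monte-Carlo slack well
inside the assertion bands.

## Known limitations

- The exact construction of the original analysis' significance test is not
  recoverable; both provided modes are principled but neither is certainly
  identical to it.
- Replicate-weight variance (BRR/jackknife), calibration/raking,
  interaction terms among sensitive covariates, multinomial outcomes and
  imputation are out of scope.
- The Charlson table is a reconstruction (above), clearly configurable.
- XPT support targets SAS transport v5 with numeric and character
  variables and 8-character names; longer names must be shortened before
  export.
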