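# Methods

## The benchmarking model

A centre's performance on an outcome is summarised as the mean patient
level (HbA1c %, LDL-Ch mmol/L, SBP mmHg) or, for severe hypoglycaemia
(≥ 1 neuroglycopaenic episode requiring third-party assistance in the
previous 12 months), as events per 100 patients. Funnel plots chart the
measure against centre size n with control limits around the pooled
value:

* continuous: `x̄ ± z · σ / √n`, with `x̄` the patient-weighted pooled
  mean and `σ` the patient-level standard deviation;
* rates: `p̄ ± z · √(p̄(1 − p̄)/n)` on the proportion scale, scaled to
  per-100 and truncated to [0, 100].

Inner limits use z = 1.96 (95%); outer limits default to z = 3, reading
the "99.8%" convention as three standard deviations (a literal two-sided
99.8% would be z = 3.09; both are configurable). Because higher levels
and rates signify worse outcomes, a centre strictly above the upper outer
limit is a *low-performing outlier*, strictly below the lower outer limit
a *high-performing outlier*; a value exactly on a limit is an inlier
(strict-inequality tie rule). No overdispersion inflation and no minimum
centre size are applied by default; both are available as options.

Risk adjustment uses the two standard provider-profiling constructions,
chosen so that unadjusted and adjusted funnels share a centre line:

* continuous outcomes: residual adjustment,
  `adj_i = y_i − ŷ_i + ȳ`, which preserves the stratum mean exactly;
* event rates: indirect standardisation,
  `adjusted rate = (observed events / model-expected events) × overall
  rate × 100`. With in-sample logistic expectations the expected total
  equals the observed total, so the pooled rate is preserved.

Whether the underlying study adjusted via residuals or O/E ratios is not
recoverable from its text; both constructions are implemented and the
defaults are documented here as this package's choice. Adjusted-funnel
dispersion is recomputed from the adjusted values.

A centre's transition from unadjusted outlier to adjusted inlier is a
*false positive*; from inlier to outlier a *false negative*. The
misclassification rate is `100 × false positives / unadjusted outliers`
of that class, reported raw and rounded to the integer percentages used
in audit reporting, and undefined (blank) when a class has no unadjusted
outliers.

## Risk models

Eight models: {T1DM, T2DM} × {HbA1c, LDL-Ch, SBP, severe hypoglycaemia}.
Candidates are age and disease duration (per decade, so coefficients read
"per 10 years"), sex (ref male), country of birth (ref Australia), BMI
category (ref healthy: <18.5, 18.5–24.9, 25–29.9, 30–39.9, ≥40 kg/m²),
DCSI complication-severity category (ref 0; 1–2, 3–4, ≥5), and smoking
history (ever vs never). Fasting status at the lipid draw is forced into
the LDL-Ch models on a-priori grounds and never removed.

Selection is forward-stepwise with backward pruning: each cycle enters
the most significant absent candidate if its joint Wald p < 0.01 (ties go
to the earlier term in the documented candidate order), then repeatedly
removes the least significant retained non-forced term while its
p > 0.05. Categorical factors enter and leave as blocks judged by a joint
Wald chi-square; single terms by the Wald z (identical at 1 df).
Complete cases are taken once over the outcome and the full candidate
set, so p-values are comparable across steps. The loop stops when a full
cycle changes nothing; a revisited state or 50 cycles raises an error
naming the oscillating terms.

Before selection, the candidate design is screened for collinearity:
per-column VIFs (1/(1 − R²) of each column on the rest), a term's VIF
being the maximum over its dummy columns. While any term exceeds the
cut-off of 10, the offender with the smaller maximum |z| in an outcome
fit is dropped (ties drop the later term). A constant numeric column is
an error; an all-zero dummy (category level absent in the data) is simply
omitted from the design, the usual omitted-level behaviour — a term only
errors when *all* its levels collapse.

Reported statistics are Wald and normal-based for both families
(z = coef/SE, two-sided p, 95% CI = coef ± 1.96·SE); logistic
coefficients are also reported as odds ratios with exponentiated CIs.
Fit statistics: adjusted R² = 1 − (1 − R²)(n − 1)/(n − p − 1) for linear
models; for logistic models the ROC area computed by the Mann–Whitney
rank statistic (ties count ½). Model fitting itself is delegated to
statsmodels OLS/Logit; everything around it (selection, screening,
reporting) is implemented here.

## Sensitivity analyses

**Tukey fences.** Outcome outliers are values outside
[Q1 − k·IQR, Q3 + k·IQR], k = 1.5, with quartiles by linear interpolation
between order statistics (the numpy default; the convention is pinned by
tests and configurable via k). The refit reruns selection on the fenced
data and reports terms gained and lost; exclusion that empties a
categorical level present in the original complete cases is an error
naming the level.

**Multiple imputation.** Numeric fields with substantial missingness are
imputed under a joint multivariate-normal model by data-augmentation
Gibbs sampling (statsmodels `BayesGaussMI`): alternate draws of missing
cells from their conditional normals and of the mean/covariance. Defaults:
m = 10 completed datasets, 200 burn-in sweeps, 50-sweep thinning —
conventional values at this data scale; observed cells are never altered.
Categorical variables are not imputed (the joint-normal model is stated
for numeric variables; in practice the high-missingness fields are LDL-Ch,
HbA1c and BMI). Per-dataset fits are combined by Rubin's rules: pooled
estimate = mean; total variance = within + (1 + 1/m)·between; df by the
standard small-sample formula (infinite when between-variance is zero).

**Treatment stratification.** Selection is rerun within the on-insulin
and not-on-insulin strata; the report lists coefficients whose sign flips
against the pooled model. Strata too small to fit are skipped with a
warning.

## The synthetic cohort generator

The generator emulates a national audit: each of `n_centres` centres
contributes 30–160 consecutive patients (uniform; configurable), each
patient T2DM with probability 3496/4670, else T1DM.

Covariates are drawn from per-type marginals matching the audited
population: category frequencies normalised over non-missing counts; age
and duration from shifted gamma distributions whose shape is solved so
the IQR/median ratio matches the printed quantiles (skew-preserving with
exactly the two printed anchors). Disease duration is resampled until it
does not exceed (integer) age. Covariates are otherwise independent
within type, except that the DCSI category receives an ordinal-logit tilt
of 0.5 per decade of duration above/below the type median — long-duration
patients carry more complications, giving the case-mix confounding the
benchmarking analysis is about. Fasting status at the lipid draw is not
reported in the audit summary; 30% fasting is assumed.

Outcomes follow the published risk-model coefficients as generating
truth: continuous outcomes as `intercept + Xβ + centre effect +
N(0, residual SD)` with residual SDs equal to the printed population SDs,
clipped to physiologic bounds (HbA1c 3–20%, LDL 0.1–15 mmol/L, SBP
60–260 mmHg); severe hypoglycaemia as Bernoulli(inverse-logit(linear
predictor + centre effect)) with log-odds-ratio coefficients. Intercepts
are not published; they are calibrated against a fixed internal
50,000-patient covariate sample so the population mean/rate hits the
printed target (8.2% HbA1c in T2DM, 13% severe hypoglycaemia in T1DM,
etc.), making them pure functions of the configuration.

Two centre-level mechanisms are available, both off by default:

* `centre_effect_sd` — true quality differences, additive per-centre
  Gaussian shifts on the linear predictor (logit scale for severe
  hypoglycaemia); the `true_effect_scenario` preset uses SDs 0.5% HbA1c,
  0.3 mmol/L LDL, 5 mmHg SBP, 0.6 logits.
* case-mix imbalance — per-centre Gaussian shifts of mean age and
  duration. The audit reports no between-centre case-mix spread, so its
  degree is a free simulation parameter; the `confounded_scenario` preset
  uses SD 12 years (age) and 6 years (duration), i.e. young-adult clinics
  versus geriatric services, with zero true centre effects.

Missingness is applied per field, independently, completely at random;
defaults are zero, with a preset reproducing the audit's observed
denominators (~10–15% on BMI, smoking, country and lipids).

What the generator does *not* emulate: joint covariate structure beyond
the duration–severity tilt (real age/BMI/smoking correlations are
absent), longitudinal visits, non-random missingness, gestational and
"other" diabetes, and socio-economic confounders. Passing tests therefore
demonstrate the statistical machinery under known truth — coefficient
recovery, correct null coverage, confounding removal — not that the
specific published coefficient values would be recovered from real audit
data.

## Numerical choices and problem sizes

* Stepwise tie-breaks (1e-15 slack), the on-limit inlier rule, and the
  drop-the-later-term VIF tie rule make every analysis deterministic for
  a fixed seed; all stage seeds derive from one top-level seed.
* Logistic fits use Newton MLE with a 200-iteration cap; separation or
  non-convergence raises rather than returning unstable estimates.
* Rate limits use the normal approximation (matching smooth funnel
  curves); small-n exactness can matter below ~30 patients per centre.
* Test and acceptance problem sizes are chosen to be informative on a
  single CPU: null coverage at 10,000 centres × 100 patients;
  coefficient-recovery coverage over 100 cohorts of n = 3,496; the
  confounding-removal property over 200 replicates of 30 centres × 100
  patients across the three continuous outcomes; MI checks at n ≈ 4,000
  with shortened (100/20) burn-in/thinning.

## Known limitations

* Stepwise inclusion at n in the millions admits tiny spurious effects at
  the fixed p < 0.01 threshold; the thresholds mirror audit practice, not
  an information criterion.
* The adjusted R² of models fitted to synthetic cohorts exceeds the
  published values because independently drawn covariates inflate
  explained variance relative to real correlated case mix.
* Residual adjustment assumes the risk model is transportable across
  centres; centre-by-covariate interactions are out of scope.
* The MVN imputer draws from the global NumPy RNG (a property of the
  underlying sampler); `impute_mvn` seeds and restores that state, so
  runs are reproducible but not parallel-safe within a process.
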