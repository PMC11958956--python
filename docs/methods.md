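# Methods

This package implements a complete environmental-epidemiology analysis
linking three urinary anions — perchlorate, nitrate and thiocyanate (PNT),
all inhibitors of the sodium/iodide symporter — to two biological-aging
scores, together with a synthetic survey-cohort generator that makes every
stage testable against known ground truth. This note records the models,
the defaults and why they were chosen, the numerical decisions, and what
the synthetic studies do and do not demonstrate.

## Aging outcomes

**Phenotypic age** maps nine blood biomarkers plus chronological age
through a fixed linear predictor

    xb = -19.907 - 0.0336 albumin + 0.0095 creatinine + 0.1953 glucose
         + 0.0954 ln(CRP) - 0.0120 lymphocyte% + 0.0268 MCV + 0.3306 RDW
         + 0.0019 ALP + 0.0554 WBC + 0.0804 age,

a Gompertz 10-year mortality score
`M = 1 - exp(-1.51714 e^xb / 0.0076927)`, and the age-scale transform
`141.50 + ln(-0.00553 ln(1-M)) / 0.09165`. Because
`ln(-ln(1-M)) = const + xb`, phenotypic age is exactly affine in `xb` with
slope `1/0.09165 ≈ 10.91` years per xb unit — a fact the generator
exploits for exact effect injection (below). The constants ship in a
versioned text file with their unit convention (albumin g/L, creatinine
umol/L, glucose mmol/L, CRP mg/dL entering as natural log, lymphocyte %,
MCV fL, RDW %, ALP U/L, WBC 1000 cells/uL); the table reader warns — but
does not reject — when more than 5% of a column falls outside broad
plausibility screens, since the coefficients are unit-bound and silent
unit errors would otherwise produce garbage quietly. The leading constant
is carried as the printed 141.50 (the original publication's 141.50225
differs by a constant 0.002-year shift). CRP values below 0.01 mg/dL are
floored there before the log (configurable); the choice only affects a
handful of near-zero laboratory values.

**Klemera-Doubal (KDM) biological age** regresses each of eight biomarkers
on chronological age by OLS (slope `k_j`, intercept `q_j`, residual RMSE
`s_j` with denominator n-2, variance explained `r_j^2`) and combines them
as

    BA = [ sum_j (x_j - q_j) k_j / s_j^2 + CA / s_BA^2 ]
         / [ sum_j k_j^2 / s_j^2 + 1 / s_BA^2 ],

i.e. the precision-weighted estimate `BA_E` shrunk toward chronological
age with weight `1/s_BA^2`, where

    s_BA^2 = Var_n(BA_E - CA)
             - (1 - r_char^2)/r_char^2 * (CA_max - CA_min)^2 / (12 m)

and `r_char` is the `k_j/s_j`-weighted average of the signed correlations
`r_j = sign(k_j) sqrt(r_j^2)`. Decisions: the clock is trained on the
analysis sample itself (no external reference population is assumed) and
the fitted parameters serialize to key-value text so scoring is
reproducible; `r_j` carries the sign of `k_j` so that negatively
age-trending biomarkers do not cancel the average; a non-positive
`s_BA^2` — possible in near-noiseless data where the correction term
dominates — is floored at 1e-8 with a warning, which leaves the estimator
exact in the noiseless limit (shrinkage weight then pins BA to CA, which
is also where BA_E sits). A biomarker whose fitted slope is numerically
zero is rejected by name, because the estimator divides by `k_j`.

## Exposure preprocessing

The fixed pipeline order is: LOD imputation -> creatinine correction ->
natural log (main path), or LOD imputation -> covariate-adjusted
standardization -> log (sensitivity path). Values below the limit of
detection are coded LOD/sqrt(2) on the measured concentration scale —
imputation is defined on that scale, which is why it precedes the
creatinine step. Creatinine correction divides ug/L by urinary creatinine
in g/L (1 mg/dL = 0.01 g/L), yielding ug/g creatinine.

The covariate-adjusted standardization fits `ln(creatinine) ~ age + sex +
race + BMI category` (creatinine is log-normal, so the linear model lives
on the log scale), predicts `C_hat = exp(fit)`, and rescales each analyte
by `C_hat / C`. This removes only the *residual* (hydration) component of
creatinine, leaving covariate-driven (muscle-mass-like) components out of
the exposure — avoiding the over-adjustment that plain ratio correction
produces when covariates drive creatinine itself.

Quartile cut points are survey-weighted 25th/50th/75th percentiles by
default (unweighted available via argument); whether the motivating
analysis weighted its cut points is not stated, so the choice is exposed.
The weighted percentile definition is the inverse weighted empirical CDF
with linear interpolation and plotting positions `(C_i - w_i)/(W - w_n)`,
which reduces exactly to the standard type-7 definition under equal
weights. Quartiles are computed on the corrected (not log) scale; the log
is monotone so labels are identical either way.

## Design-based survey regression

Point estimates are weighted least squares; variance is the Taylor
linearization estimator: per-PSU totals of weighted score vectors
`w_i x_i e_i`, centered within stratum, combined as
`sum_h n_h/(n_h - 1) sum_i (z_hi - zbar_h)(z_hi - zbar_h)'` and
sandwiched by `(X'WX)^{-1}`. Design degrees of freedom are
`#PSU - #strata`; confidence intervals and single-coefficient p-values use
the t distribution at that df. Joint Wald tests (spline nonlinearity,
interaction products, categorical sex differences in the descriptive
table) use the Hotelling T-squared reference,
`T2 (df - q + 1)/(df q) ~ F(q, df - q + 1)`: with a covariance estimated
at ~45 design df the unscaled form was measurably liberal in the null
calibration study (rejection 0.072 vs 0.064 at nominal 0.05 over 500 null
replicates), and the Hotelling form is the exact reference under Wishart
sampling of the covariance. A 1400-replicate calibration study of the
model-3 exposure coefficient found the point estimate unbiased and
`mean(se^2)/var(beta) = 1.03 +- 0.045` — the variance estimator is
calibrated; a literal 2-SE band then covers ~94.9% (the t(45)
expectation), not 95.45%.

Strata with a single PSU (possible after subsetting) are handled by
`adjacent-collapse` (merge with the neighboring stratum in sorted label
order) by default; `certainty` (zero variance contribution) and `fail` are
selectable. Covariate sets: model 1 = age, sex, race/ethnicity; model 2
adds income ratio, BMI category, marital status, home ownership,
education, physical activity, smoking and drinking; model 3 adds
hypertension, diabetes, cardiovascular disease, cancer, energy intake,
diet score and survey cycle. Categorical covariates enter as drop-first
dummies; each model is complete-case with the analyzed n recorded.

The trend test recodes quartiles as the continuous score 1-4 and reports
that term's p-value (weighted within-quartile medians available via
argument). Restricted cubic splines use the Harrell truncated-power basis
(k-1 columns, exactly linear beyond the boundary knots, normalized by the
squared knot span) with 4 knots at the 5/35/65/95th percentiles by default
(3 or 5 knots selectable; the motivating analysis states no knot count).
`P-nonlinear` jointly tests the k-2 nonlinear coefficients; `P-overall`
all spline coefficients. Subgroup analyses fit per-level models plus a
pooled model with exposure-by-modifier product terms; the interaction
p-value is the joint Wald test of those products, with the modifier
removed from the covariate set when it is the stratifier.

## Weighted quantile sum regression

Exposures are scored into within-training-sample quartiles (cut points
reused on the test split; scores are rank-based, so the index is invariant
to monotone transforms of the raw exposures). The data are split 40%/60%
into training and test sets. On each of `n_bootstrap` resamples of the
training rows, the Gaussian likelihood of
`y ~ b0 + b1 (sum_m w_m q_m) + covariates` is maximized with `w` on the
probability simplex and `b1` sign-constrained, via the unconstrained
reparameterization `w = softmax(theta)`, `b1 = sign * exp(phi)`; covariate
coefficients are profiled out exactly by residualizing `y` and the scores
on the covariates (Frisch-Waugh), leaving a 4-parameter smooth
optimization solved by L-BFGS-B with an analytic gradient. Non-converged
resamples are dropped and counted; more than 20% dropped is a hard
failure. Final weights average the resamples with index |t| >= 1
(signal-filtered mean, the common practice; plain mean selectable). The
index is then built on the test split with the final weights and the test
regression of outcome on index plus model-3 covariates provides the
coefficient, CI and p-value. The test-split coefficient is deliberately
left *unconstrained*: the sign constraint shapes weight estimation only,
so a positively-constrained index can legitimately report a negative
test-split association. Survey weights are not used in weight estimation
(mixture methods are not design-aware); they can optionally be applied to
the test-split regression. With one exposure the weight is exactly 1 and
no optimization runs.

## Bayesian kernel machine regression

The model is `y = h(z) + X beta + eps` with Gaussian noise and a
Gaussian-process prior on `h` with kernel
`lambda sigma^2 exp(-sum_m r_m (z_m - z'_m)^2)` on standardized exposures.
Each kernel scale has a spike-and-slab prior: excluded (`r_m = 0`) with
probability 0.5, else an Exponential(1) slab — weakly informative on the
standardized scale. When *every* component is excluded the exposure
surface is dropped entirely (`K = 0`), so the all-excluded state is exact
linear regression rather than a free random intercept (the all-ones kernel
that `r = 0` would otherwise imply). Remaining priors: Gamma(1, 0.1) on
`lambda`, inverse-gamma(2, 1) on `sigma^2`, N(0, 100^2) on covariate
coefficients.

Sampling is Metropolis-within-Gibbs on the marginal likelihood with `h`
integrated out (`y - X beta ~ N(0, sigma^2 (I + lambda K))`, evaluated by
Cholesky): conjugate updates for `beta` and `sigma^2`; a log random walk
for `lambda` (proposal SD 1.3); and per-component birth/death/jitter moves
for `(delta_m, r_m)` — birth draws from the slab prior, death and birth
carry the prior odds and proposal asymmetry, jitter is a log random walk
(SD 1.3). Proposal scales were set so that lambda and jitter acceptance
rates sit in (0.1, 0.6) on default synthetic data, and acceptance rates
are recorded on the posterior object. Defaults: 2,000 iterations with 50%
burn-in and no thinning (the motivating analysis ran 10,000; the
conditional posterior inclusion probabilities — the posterior means of the
inclusion indicators — are stable well before that at these sizes).
Because the kernel matrix is n x n, fits are capped at n = 1,000 and
larger inputs are subsampled with a warning.

Exposure-response summaries (univariate curves, the joint "overall effect"
contrast of all exposures at percentile p versus the 50th, single-exposure
75th-vs-25th contrasts with co-exposures fixed at their 25/50/75th
percentiles, and bivariate curve families) are computed from the GP
conditional mean and covariance at the requested points, one Cholesky per
retained draw with all points batched; credible intervals come from one
Gaussian draw of the contrast per posterior draw. A contrast of a point
with itself is exactly zero with a zero-width interval. Chains are
bit-reproducible given the seed; conPIPs are statistically (not
bit-level) equivariant to exposure relabeling, since a single RNG stream
serves all components.

## Synthetic cohort generator

The generator emulates the structure of a three-cycle national
examination survey: ages uniform on 20-80; each biomarker linear in age
with Gaussian noise at NHANES-plausible slopes, intercepts and SDs; 45
strata (three cycles of 15) with 2 PSUs each assigned round-robin;
log-normal examination weights (dispersion 0.5, CV ~0.53) rescaled to sum
to n, with dispersion 0 giving exactly equal weights — which is what makes
the weighted-vs-unweighted sensitivity contrast meaningful. The three
anions are jointly log-normal on the excretion (ug/g) scale with pairwise
correlation 0.37 — the observed association range for these analytes —
and medians near U.S. adult levels (perchlorate 3.5 ug/g, nitrate 44,000
ug/g, thiocyanate 1,400 ug/g); log-normal marginals are an assumption
(standard for urinary analytes), not a reported fact. Measured
concentration is excretion times a log-normal creatinine dilution factor,
then left-censored at per-analyte LODs on the concentration scale (0.05 /
700 / 20 ug/L — these assays detect essentially everyone, so the censored
fraction is realistically tiny; tests exercise the imputation path with
raised LODs). Covariate effects on creatinine (e.g. +0.4 ln-units for
males) raise *measured* creatinine without touching the dilution factor,
so plain ratio correction over-adjusts exactly as it does in real data
while the covariate-adjusted standardization recovers the truth.
Categorical covariates are independent draws at approximately the
motivating cohort's prevalences; confounding (covariate -> exposure and
covariate -> outcome jointly) is injectable via configuration.

True exposure effects (years per ln-unit of excretion, centered at the
configured log-mean) are injected by inverting the clock transforms onto
one biomarker per clock: phenotypic age is affine in xb, so adding
`delta * 0.09165 / 0.3306` to RDW shifts phenotypic age by exactly
`delta` years; KDM biological age is linear in each biomarker given the
training parameters, so SBP absorbs the KDM effect using the
pre-injection fit (exact up to the small change in the refitted `s_sbp`).
The two clock panels are disjoint synthetic columns precisely so these
injections never cross-contaminate. All draws flow through a single
seeded generator in a fixed order; identical configurations are
byte-identical.

What the generator does **not** emulate: multi-stage selection
probabilities and nonresponse adjustment (weights are outcome-independent
noise, so weighted and unweighted fits agree up to sampling error by
construction); intra-PSU correlation (rows are independent, so the
design-based variance is conservative-neutral rather than stress-tested
against clustering); measurement error and within-person variability of
spot-urine exposures; missing data beyond LOD censoring. Passing tests
therefore demonstrate correctness of the estimators under the stated
model, not robustness to these real-data features.

## Study sizes used by the test suite

The acceptance-style studies use: 1,000 random vectors for the
phenotypic-age formula oracle; n = 5,000 for KDM parameter recovery; 500
replicates at n = 1,000 for the null type-I studies; 200 replicates at
n = 2,000 for effect recovery; n = 3,000 with 200 bootstrap resamples for
WQS weight recovery (the constructed outcome uses residual SD 1.0 against
a -0.8-per-quantile-unit index, a signal-to-noise at which the bootstrap
weight distribution concentrates); 20 seeded BKMR runs at n = 400 with
2,000 iterations; and a full pipeline run twice at n = 700 for
byte-identity. The full-pipeline defaults (WQS 100 bootstraps, BKMR 500
iterations with a 300-row cap) are deliberately desk-scale; production
settings (10,000 bootstraps/iterations) are plain configuration changes.

## Known limitations

- The design-based variance uses the plain linearized sandwich; a literal
  2-SE band therefore covers ~94.9% at 45 design df, and no
  leverage-style (CR2/jackknife) refinement is applied to model fits.
- WQS and BKMR do not honor the survey design during estimation (the
  field's standard implementations share this limitation).
- BKMR is O(n^3) per likelihood evaluation; the n-cap/subsample policy
  trades population coverage for tractability rather than implementing
  low-rank kernel approximations.
- The exclusion cascade is configurable predicates (age >= 20,
  completeness) rather than a fixed rule set.
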