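# Methods

## Model and procedure

Each biomarker is analyzed independently on the standardized scale
(z-scored across all retained subject-visits, sample sd with n−1). The
per-observation model is linear in five risk factors — age (years), disease
state DS (ordinal 1–4 used numerically), sex (0/1), education (years),
apoe-ε4 allele count (0/1/2) — and all 10 pairwise products, plus an
intercept: 16 fixed coefficients in a fixed column order
(`mfdpm.design.DESIGN_COLUMNS`). Three nested error structures are fitted:

1. **fixed_robust** — no random effects; iteratively reweighted least
   squares with Tukey bisquare weights (statsmodels RLM), coefficient
   convergence 1e-8, at most 50 sweeps. If the residual MAD scale is
   numerically zero the exact least-squares solution is returned (the
   M-estimator is undefined at zero scale).
2. **mixed_intercept** — adds a subject random intercept.
3. **mixed_intercept_slope** — adds a subject random age slope with a full
   2×2 random-effects covariance.

Variants 2–3 are fitted by maximum likelihood (not REML, so likelihoods are
comparable across variants) using an in-package profiled-likelihood
optimizer (`mfdpm.lmm`): given the scaled random-effects covariance
Ψ = LL′, the fixed effects and residual variance have closed-form GLS/ML
solutions, leaving a 1–3 parameter objective optimized by Nelder–Mead in
the Cholesky parameterization. The boundary Ψ → 0 is an interior point of
that parameterization, so zero variance components are estimated without
special casing and reported as boundary fits. For the random-slope design
the age column is centered during optimization — an exact
reparameterization absorbed by the full covariance — and the covariance is
mapped back to raw-age units for reporting. The optimizer reproduces
statsmodels MixedLM log-likelihoods to ~1e-4 on well-conditioned problems
(asserted in the test suite, where MixedLM serves as an independent
oracle); it exists because the analysis resamples fits thousands of times
and needs each fit to cost ~0.1 s and to be robust at boundary optima.

Model choice minimizes `BIC = k ln(n_obs) − 2 log L` with k counting the 16
betas, the residual variance and the random-effects covariance parameters
(0, 1 or 3). For the robust variant the Gaussian log-likelihood is
evaluated at the robust coefficients with the MLE residual variance; this
is an approximation (no likelihood is defined for an M-estimator), chosen
so that on clean data — where the robust fit coincides with OLS — variant
comparisons reduce to exact ML comparisons.

**Marginalization.** The nuisance covariates (sex, education, apoe-ε4) are
averaged out of the fixed-effects predictor. Because the predictor is
linear with pairwise interactions, the covariate average collapses to four
effective coefficients: g(age, DS) = a₀ + a_age·age + a_DS·DS +
a_ageDS·age·DS, computed from the covariates' first moments and pairwise
product moments. Two weightings are available: `uniform` (each covariate
uniform from its observed minimum to maximum, categories equally weighted;
products factorize by independence) — the default — and `empirical`
(observed joint frequencies, so correlated covariates are handled exactly).
Random effects have population mean zero and drop out. The closed form is
verified against a brute-force dense-grid average to ≤ 1e-10.

**Trajectories and abnormality.** g is evaluated on the inclusive weekly
grid of 1,560 ages from 40 to 70 years while DS ramps from 1 to the
terminal state of each transition (2, 3 or 4), linearly by default or along
a logistic ramp (default midpoint 55 y, steepness set so 5%→95% of the rise
spans 20 years, endpoints matched exactly by normalization). Intermediate
transitions reach their terminal DS exactly at age 70 so all four
transitions live on one grid. Abnormality is the pointwise absolute
difference from the same biomarker's HC→HC trajectory; indices integrate it
by the trapezoid rule, normalized by K = the maximum area over the
biomarker set passed in (all biomarkers jointly by default; per-panel
normalization is a caller choice). Stage ages for the intermediate indices
are where the HC→LOAD DS ramp first reaches 2 and 3 (50 and 60 years on the
linear ramp).

**Ordering.** The hierarchical matrix compares factor pairs at every
(region, grid point); the strictly larger factor scores 1 and exact ties
score 0.5 each, so H[i][j] + H[j][i] = 100 identically (ties are measure
zero on real data but common on synthetic constructions). Regional
vulnerability weights are the regions' summed total indices across factors,
normalized to sum 1; factor curves are the weight-averaged regional
abnormality curves (scalar biomarkers join unweighted) divided by the
single global maximum. The factor ranking orders curves by area under the
curve, ties broken alphabetically and flagged.

**Bootstrap.** Subjects are resampled with replacement (visits travel with
their subject, duplicated draws become distinct grouping units), preserving
the within-subject correlation the mixed model assumes. Standardization,
like quality control, is applied once before resampling, so a noiseless
cohort yields exactly zero-width bands. Per-replicate seeds derive from the
root seed by counter. Summaries are replicate means with 2.5/97.5
percentile bands; replicates whose fit fails (e.g. a resample losing a
covariate level and collapsing an interaction column) are logged and
skipped, and more than 20% failures abort the run.

**Quality control** runs in fixed order. (i) Subjects with ≥ 2 distinct DS
values are removed. (ii) Each subject's multimodal feature vector
(visit-averaged, region-averaged value per factor plus scalars) is scored
by its leave-one-subject-out Gaussian class-conditional log-density under
its own diagnostic group, rank-normalized within group to (0, 1]; subjects
strictly below the 10th within-group percentile are removed (within-group
so the smallest group is not disproportionately deleted; strict inequality
so all-tied scores remove nobody). (iii) Within each clinical group,
records whose squared Mahalanobis distance exceeds the χ²(d) 1−α quantile
(α = 0.05) are deleted for that biomarker/modality only; imaging factors
are tested as full region vectors (d = number of regions), scalars
individually. When n ≤ d or the empirical covariance is ill-conditioned, a
Ledoit–Wolf shrinkage covariance is used while d for the χ² reference
remains the full feature count.

## Synthetic cohorts

The generator draws, per subject: baseline age uniform over 40–70 y with
yearly visits; sex Bernoulli(0.5); education uniform integer 6–20 y;
apoe-ε4 multinomial (0.6, 0.3, 0.1); a DS group from proportions
(0.35, 0.25, 0.20, 0.20) held constant across visits. Biomarker values
follow the exact model above: the 16-coefficient linear predictor plus a
subject random intercept (sd 0.3), a random age slope (sd 0.01/y) and
Gaussian noise (sd 1.0) — defaults chosen as plausible desk-scale stand-ins
since the reference cohort's schedules and covariate distributions are not
public. The factor ordering is planted through factor-specific |β_DS|
magnitudes (default descending with adjacent gaps 0.25 sd from a base of
0.5), which under the linear model makes the abnormality-curve area
monotone in |β_DS|, so the recovered order is predictable from the
configuration. Converters (a later-visit DS increment) and outliers (a
+magnitude × within-group-sd shift on chosen records) are planted from
independent named random streams of the root seed, so planting never
perturbs the cohort draws. What the generator does *not* emulate: missing
data, visit-schedule irregularity, non-linear trajectories, measurement
batch effects, spatial correlation between regions, and realistic
covariate-DS confounding — so green tests demonstrate correctness of the
pipeline under its own model assumptions, not robustness to real-data
violations of them.

## Numerical choices and edge cases

- Convergence tolerances 1e-8 (robust coefficients, profiled
  log-likelihood) with iteration caps 50/200; all configurable.
- BIC ties go to the fewer-parameter variant.
- Constant biomarkers (sd 0) are excluded at standardization with a
  warning rather than divided by zero.
- Rank-deficient designs raise an error naming the collinear columns.
- An all-zero abnormality set leaves K undefined; indices are reported as
  0 with a warning. The residual variance in likelihoods is floored at
  1e-12 so noiseless fits keep finite BICs.
- Degenerate single-visit cohorts fit with a warning that the intercept
  variance is not identifiable against noise.

## Problem sizes

Validation runs use desk-scale configurations chosen as the package's own
defaults: ordering recovery at 300 subjects × 4 visits × 10 regions ×
5 factors over 50 replicates; BIC selection consistency at 2,000
observations × 100 replicates per variant on a reduced
intercept+age+DS design (selection consistency concerns the variance
structure, not the fixed-effects dimension); bootstrap coverage at 100
subjects with B = 100 over 20 replications. The acceptance script runs 120
subjects × 3 visits × 3 regions with the full three-variant fit.

## Known limitations

- Everything is linear in age and DS; no basis expansions.
- The likelihood-score construction for QC step (ii) and the exact
  marginalization weights are this package's documented choices among
  several defensible ones.
- Percentile bootstrap only (no BCa), and no imputation of QC-removed
  values.
- The robust-variant "likelihood" is a working approximation; BIC
  comparisons involving heavy contamination should be read with that in
  mind.
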