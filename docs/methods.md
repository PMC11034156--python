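# Methods

## The harmonization model

`combatstab` implements parametric ComBat for two-site (or generally
multi-site) feature tables. Each feature *f* on participant *i* at site *s*
is modeled as

    Y_isf = α_f + X_i β_f + γ_sf + δ_sf ε_isf ,   ε_isf ~ N(0, σ_f²),

where X collects biological covariates whose variation must be preserved,
γ_sf is the additive and δ_sf the multiplicative site effect.

**Standardization.** Per feature, Y is regressed by least squares on the
covariates plus a full set of site indicators (no intercept). The
sample-size-weighted mean of the site coefficients becomes α̂_f; the
re-centered site coefficients become γ̂_sf, which therefore satisfy the
identifiability constraint Σ_s n_s γ̂_sf = 0 exactly (tested to 1e−8 of the
feature scale). σ̂_f² is the mean squared residual with the 1/N divisor —
deliberately not the unbiased N−p divisor, matching the model's printed
definition and the reference implementation. Z_isf = (Y − α̂ − X β̂)/σ̂.

**Empirical Bayes.** Per site, the raw estimates are the per-feature mean
(γ̂, in Z units) and unbiased variance (δ̂², ddof=1) of Z. Hyperpriors pool
across features by method of moments: γ ~ N(ḡ, τ²) with ḡ, τ² the
cross-feature mean/variance of γ̂; δ² ~ InvGamma(a, b) with (a, b) from the
inverse-gamma moment inversion a = m²/v + 2, b = m(a−1) applied to the
cross-feature mean m and variance v of δ̂². The conditional-posterior
updates

    γ* = (τ² n_s γ̂ + δ*² ḡ) / (τ² n_s + δ*²)
    δ*² = (b + ½ Σ_i (Z_isf − γ*)²) / (n_s/2 + a − 1)

are iterated until the maximum absolute change in (γ*, δ*²) falls below
`conv` (default 1e−4; `max_iter` 100, non-convergence raises with the last
change). On typical cohorts convergence takes 3–5 iterations. The absolute
stopping rule differs from sva's relative one; with either rule both
implementations agree to ~1e−8 at tight tolerances (verified against
`sva::ComBat` in the test suite).

**Adjustment.** Ŷ = σ̂ (Z − γ*)/δ* + α̂ + X β̂. A `no_eb` mode substitutes the
raw per-site moments of Z for (γ*, δ*), which makes per-site means and
variances exactly equal after adjustment — used for exact invariant tests
and available as a harmonization variant.

Covariate coding: continuous covariates enter untransformed, binaries as
0/1, the categorical race as one-hot with first-level reference. A covariate
that is constant in the sample (common in small subsamples, e.g. no MCI
cases at N=36) is dropped with a warning: it carries no variation to
preserve and would be collinear with the site indicators.

## The synthetic cohort generator

The generator draws directly from the model above, so every downstream
stage can be scored against known truth. Defaults emulate a demographically
matched two-site aging cohort: 159 participants per site; ages uniform on
(59.8, 91.9) location-shifted to per-site means 73.9/74.0 (uniform is the
simplest distribution consistent with reporting only a mean and range); 59%
male; 6% MCI; APOE2 18/16%, APOE4 28/29%; non-Hispanic-white 84/94%;
education N(17.0, 2.5)/N(16.3, 2.5); 112 features on a fractional-
anisotropy-like scale (levels α_f ~ U(0.30, 0.60), residual SDs
σ_f ~ U(0.015, 0.035)). Feature effects: age slopes ~ N(−0.0015, 0.0005²)
per year (FA declines with age), modest sex and diagnosis effects; race,
education and APOE effects are zero by default (they are generated and
carried but do not move features) with an `all_covariate_effects` switch.

Site effects follow the priors ComBat assumes: γ_sf ~ N(±0.010, 0.005²) —
shifts of roughly a third to a half of a residual SD, a realistic
scanner-difference magnitude — and δ_sf² ~ InvGamma(25, 24) / InvGamma(25,
26), i.e. scale ratios centered near 1 with ~15% spread. Setting a
`SitePrior` to all zeros yields γ = 0, δ = 1 exactly (the null sentinel).
Residuals are normal by default; `student-t` (default df 5) rescaled to SD
σ_f exercises the heavy-tailed regime observed in real DTI features. The
inverse-gamma prior governs δ² (not δ); the diagnostics default to the same
convention with a flag for the literal-δ reading.

`generate_matched_cohort` (the "silver standard" fixture) builds cross-site
pairs sharing sex and diagnosis with ages jittered within ±3.5 years plus
the between-site mean offset, guaranteeing the ≤ 4-year matching bound by
construction. All draws flow from one `numpy` Generator seeded by
`CohortConfig.seed`; identical config ⇒ byte-identical CSV output.

What the generator does *not* emulate: spatial correlation between ROI
features (features are independent given the covariates), non-linear age
trajectories, scanner drift within site, missing data, and
covariate-dependent site effects. Passing tests therefore demonstrate
correctness of the machinery and its behavior under the model's own
assumptions (plus the heavy-tail violation), not performance on any real
cohort.

## The bootstrap experiment

The grid crosses total sample size (19 levels by default: 12–96 roughly
log-spaced, then 108–306 in steps of 18; the fine-grained upper range is
where stability thresholds live), imbalance ratio X:10 for X = 1..10 (site 1
is the fixed-denominator site; only site 2's count varies), and target
between-site mean-age difference {0, 2, 4, 6, 8, 10} years, each nonzero
shift in both directions. The integer split of N under X:10 rounds the
varying site's share half-away-from-zero with the remainder to the fixed
site. A cell is feasible iff both sites keep ≥ 6 participants, the targets
fit in the site pools, and the target shift is attainable within ±1 year
(checked against the extreme-selection bound: oldest-n mean minus
youngest-n mean).

Subsampling is without replacement. Shift targeting uses exponential age
tilting — per-site weights ∝ exp(λ(age − mean)) with λ = (target −
pool mean)/pool variance, the standard exponential-tilt first-order choice —
with rejection until the realized shift is within ±1 year (budget 200
attempts; exhaustion marks the run skipped, mirroring the exclusion of
unattainable cells). Every run's seed derives from the master seed and the
(cell, iteration) coordinates via `numpy.random.SeedSequence`, so single
runs reproduce in isolation and the whole sweep is bit-reproducible.

Each run is harmonized and the association model `Y ~ 1 + age + sex + site
+ diagnosis` is fit per feature by OLS (classical covariance SEs; no robust
correction). Baselines: the same OLS on unharmonized data, and a linear
mixed-effects model with a random site intercept replacing the fixed site
term (REML via statsmodels MixedLM; with only two sites the random-effect
variance is weakly identified and boundary fits are recorded per feature
rather than raised).

## Stability metrics

Errors are referenced to the silver-standard fit treated as fixed truth:
per feature, the RMSE across iterations of (run value − silver value), then
the mean over features — in that order. Metrics: standardized β_age
(normalized by the silver-standard SE per feature), γ* per site, log δ* per
site (natural log), and the between-site differences γ*_s1 − γ*_s2 and
log δ*_s1 − log δ*_s2. γ* and δ* are left unnormalized (their SEs have no
silver-standard analogue, and the EM couples them). Direction-expanded
cells are reported per direction; `tabulate_grid` pools directions by
averaging (configurable) when emitting total-N × imbalance matrices per
shift level.

## Assumption diagnostics

Residual and γ* normality are scored by the average negative log-likelihood
under a normal fitted with the sample mean and ML (1/n) SD. Note an
algebraic consequence of that recipe: the average NLL reduces identically
to ½log(2πσ̂²) + ½, so it tracks only the residual scale, not the shape of
the distribution — a variance-matched heavy-tailed sample scores the same
on average. Shape violations are instead caught by the Anderson–Darling
test (case of estimated mean and variance): corrected statistic
A²(1 + 4/n − 25/n²) against Stephens' critical values, default level 0.05;
the type-I error calibrates to 0.05 ± 0.01 in simulation. δ*² normality of
fit is scored by the average NLL under the moment-fitted inverse gamma,
computed in log space (log-gamma, no overflow across ≥ 10 orders of
magnitude). Covariate correlation uses Pearson on coded covariates
(binaries 0/1, race reference-coded, site indicator included); constant
covariates yield NaN rows/columns rather than being dropped. Per-run
diagnostics can be differenced against a silver-standard reference report.
NLLs are averaged within each unit (feature for residuals, site for γ*/δ*)
and then across units.

## Numerical and design choices

- EM stopping: max absolute change < 1e−4 over (γ*, δ*²), `max_iter` 100.
- Degenerate inputs raise with the offending feature/covariate named:
  constant features (σ̂ = 0 to within 1e−10 of scale), rank-deficient
  designs, single-site tables, zero-spread diagnostic samples (NaN inside
  sweep-level diagnostics, error at the operation level).
- Problem sizes in tests/acceptance runs: parameter recovery at per-site
  n ∈ {25, 50, 100, 200} × 10 seeds; CLT scaling on a 1,500-per-site
  no-site-effect pool at N ∈ {108..306}, B = 15 (a large pool keeps the
  without-replacement draws in the CLT regime — subsampling nearly all of a
  318-participant pool would suppress the error by the finite-population
  correction and break the 1/√N law by construction); shift degradation at
  N = 144, B = 5, 10 cohorts; AD calibration over 10,000 samples of n=100.
- The equal-means EB fixture, contraction property (γ* always between the
  raw site mean and the prior mean) and the exact no-EB equalization pin
  the shrinkage algebra independently of the sva cross-check.

## Known limitations

- Two-site designs only for the experiment grid (the ComBat core itself
  accepts any number of sites).
- Features are conditionally independent in the generator; correlated-ROI
  stability behavior is untested.
- The LME baseline with two sites estimates a random-intercept variance
  from two groups; treat `b_site` as descriptive.
- Non-parametric ComBat, ComBat-GAM, longitudinal and reference-batch
  variants are out of scope.
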