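# Methods

`mesfsurv` implements a three-stage multilevel spatial survival analysis for
patient-level time-to-event data grouped into contiguous regions (counties,
districts), together with the synthetic data machinery needed to validate
every stage without access to restricted registry records.

## Models

**Model 1 — Cox proportional hazards.** The hazard for a patient with
covariate vector *x* is

    h(t | x) = h0(t) · exp(β₁x₁ + … + β_p x_p),

with h0 unspecified. Coefficients maximize the log partial likelihood by
Newton–Raphson with step-halving; convergence requires max |score| < 1e−8 or
a relative log-likelihood change below 1e−10. Tied event times use the Efron
correction by default (monthly-grid survival times tie heavily; Efron is the
more accurate of the two standard corrections), with Breslow available. On
tie-free data the two are identical, which the tests assert. The score and
observed information are accumulated with suffix cumulative sums over the
time-sorted sample; the quadratic part of the information collapses to
`X' diag(w·a) X − X̄'X̄`, where `a_i` accumulates inverse risk-set
denominators up to each subject's time (with the within-tie Efron
adjustment) and `X̄` stacks risk-set means at event times, so one Newton
step costs two dense matrix products regardless of the number of event
times.

**Model 2 — Gaussian region intercepts (shared frailty).** The linear
predictor gains a region intercept r_g ~ N(0, σ²), i.i.d. across regions.
For fixed σ the joint vector (β, r) maximizes the penalized partial
likelihood ℓ(β, r) − r'r/(2σ²); σ itself maximizes the Laplace
approximation to the integrated log partial likelihood

    ℓ_int(σ) = ℓ_pen(β̂_σ, r̂_σ) − ½ log det(σ² H_rr + I),

where H_rr is the random-effects block of the observed information at the
penalized optimum. The outer maximization runs Brent's method on log σ over
[1e−4, 10] with tolerance 1e−5 (the bounds comfortably bracket any
plausible frailty SD on the log-hazard scale). Warm starts carry (β, r)
across outer evaluations, so inner Newton solves typically need two or
three iterations. Regions without patients keep r̂ = 0 (the prior mean), so
the output always has one intercept per region of the weights graph. The
indicator block of the design is never materialized: each row belongs to
exactly one region, so all risk-set sums over regions reduce to bincount
scatters at event-time resolution plus reversed cumulative sums (verified
numerically identical to the dense-design engine). A fixed-variance fit is
exposed as well; with σ fixed both this package and R's
`survival::coxph(frailty.gaussian(theta))` maximize the same objective, and
the two agree to ~1e−4 on test data.

**Model 3 — SSRE/SURE decomposition.** Let C be the binary contiguity
matrix over n regions and M = I − 11'/n. The eigenvectors E of the doubly
centered matrix MCM are orthogonal map patterns whose Moran coefficient is
MC_i = (n/S0)·λ_i with S0 = 1'C1. The Model 2 intercepts r̂ are regressed
on a stepwise-selected subset E_k:

    r̂ = E_k β_Ek + e,

and the survival model is refit with the selected eigenvectors expanded to
patient rows as fixed covariates plus a fresh random intercept:

    h(t | x, r) = h0(t) · exp(x'β + E_k β_Ek + r).

The fitted eigenvector component E_k β̂_Ek is the spatially structured
random effect (SSRE); the refitted intercepts r̂ are the spatially
unstructured remainder (SURE). Eigenvectors are not re-selected inside
Model 3 by default; an optional single re-selection pass against the
refitted intercepts can be enabled in the pipeline configuration.

## Eigenbasis construction

The constant vector is always a zero-eigenvalue eigenvector of MCM, and a
numerical eigendecomposition returns an arbitrary rotation of the null
space. The implementation rotates the null space so the constant direction
is isolated and drops it, leaving m = n−1 columns that are exactly
orthogonal to the intercept — the constant carries no spatial pattern and
would otherwise contaminate the regression. Signs are fixed (first
non-negligible coordinate positive) and ties in eigenvalue order are
resolved stably, so identical inputs always produce identical bases.

Candidate eigenvectors are those with MC_i / MC_max ≥ 0.25 on the positive
side — the conventional pre-filter for positive spatial autocorrelation;
the threshold, entry level (0.05) and removal level (0.10) are all
configurable.

## Stepwise selection and its error variance

Because the candidate eigenvectors are orthonormal and mean-zero, each
regression coefficient equals e_j'y regardless of which other columns are
present; only the error-variance estimate changes between steps. The
t-tests therefore use the residual variance of the model containing *all*
candidates whenever at least 5 degrees of freedom remain. This choice keeps
the false-entry rate at the nominal α per candidate under a white-noise
target; estimating the variance from the current working model instead
(naive stepwise) shrinks σ̂ as the largest coefficients are absorbed and
roughly doubles the number of spurious entries. When the candidate set is
nearly a complete basis the per-step estimate is used as a fallback. Ties
in p-value break by larger |coefficient|, then lower index, making the
procedure fully deterministic. The decomposition identity is exact by
construction: `ssre + residual = target` (the ssre component is mean-zero;
the residual carries the target mean).

## Moran's I

With binary symmetric weights,

    I = (n/S0) · Σ_ij c_ij z_i z_j / Σ_i z_i²,  z = x − x̄,

with E[I] = −1/(n−1). The analytic variance defaults to the randomization
assumption (normality available); inference is one-sided against positive
autocorrelation by default, which is how clustered map patterns are
conventionally screened (a strongly negative I then yields p near 1).
The permutation test reports the conditional pseudo p-value
(1 + #{I_perm ≥ I_obs})/(n_perm + 1), reproducible given a seed. p-values
display to four decimals, with "0.0000" meaning < 0.00005. For an
eigenvector of MCM, I equals its Moran coefficient exactly, which links the
diagnostic to the filtering construction and is asserted in the tests.

## Diagnostics

*Proportional hazards.* Scaled Schoenfeld residuals at event times are
score-tested for zero slope against event time (Grambsch–Therneau):
per-covariate chi-square on 1 df and a global test on p df. Monte-Carlo
calibration under proportional hazards holds the type-I error near the
nominal level, and a sign-reversing effect at the median is detected with
high power at n = 500.

*Collinearity.* VIF_j = 1/(1−R²_j) from regressing each design column on
the others plus an intercept; perfect collinearity reports an infinite VIF
with the offending columns named.

*Model comparison.* AIC = −2·loglik + 2·k. For the random-intercept models
the reported log-likelihood is the Laplace-approximate integrated value and
k counts fixed parameters plus one variance; the penalized value is also
emitted. Likelihood-ratio tests use 2·Δloglik against chi-square with the
configured df; adding a single variance component tested at the boundary of
its space uses the ½χ²₀ + ½χ²₁ mixture.

## Synthetic data generator

The generator emulates the structure of a state-wide end-stage renal
disease registry joined to census county covariates:

- **Map**: a rows×cols lattice (default 16×16 = 256 regions, close to a
  254-county state map), queen or rook contiguity.
- **Frailty**: a spatial part — a random-weight combination of chosen MCM
  eigenvectors rescaled so its sample SD equals `spatial_sd` exactly — plus
  i.i.d. N(0, noise_sd²) noise; both parts are recorded, so the true
  SSRE/SURE split is known.
- **Covariates**: `simple` (one Bernoulli(0.5) indicator, one standard
  normal; true log-HRs 0.5 and −0.5) or `registry`, which mirrors a
  registry covariate sheet — age group, transplant count, cause of death,
  primary disease, sex, race at the patient level and seven census-style
  rates at the region level, 24 design columns in all, with default effect
  sizes at registry-reported magnitudes (e.g. HR ≈ 4.19 for age 75+ vs
  18–44) and plausible prevalences.
- **Event times**: inverse-transform draws from an exponential (default
  rate 0.02/month, median survival ≈ 35 months at baseline) or Weibull
  baseline under the proportional-hazards model; administrative censoring
  at a fixed time, by default calibrated to the registry's ≈54.52% censored
  fraction by cutting at the matching quantile of the latent event times.
  An optional flag rounds times up to whole months to create heavy ties.

Everything is driven by a single integer seed and regenerates
byte-identically. What the generator does *not* emulate: informative
censoring mechanisms, within-region covariate clustering beyond the shared
frailty, irregular county geographies (a lattice has more homogeneous
neighbor counts than a real map), and measurement error in region
covariates — so passing recovery tests demonstrate correctness of the
estimators under the stated model, not robustness to those violations.

## Problem sizes used in the checks

Parameter recovery runs the 16×16 lattice at 200 patients/region (51,200
patients, ≈23,000 events) with true σ = 0.3, averaging 20 replicates in the
test suite (8 in the acceptance script); a fit takes ~10 s on one core. The
SSRE/SURE signature runs a scaled-down 10×10 lattice at 50 patients/region
with frailty built from the two top-autocorrelation eigenvectors
(spatial_sd = 0.3, noise_sd = 0.1), 50 replicates in the test suite (20 in
the acceptance script). These sizes were chosen as the smallest
configurations at which the Monte-Carlo tolerances of the checks are
comfortably met by the estimators' large-sample behavior.

## Known limitations

- The integrated likelihood is a Laplace approximation; with very few
  events per region its σ̂ can be biased low, and the profile can flatten
  near the lower bound (a fit reports `sigma_at_bound` when the optimum
  pins there).
- "Cause of death" in the registry-like covariate sheet is generated and
  modelled as an ordinary baseline covariate. For censored patients a real
  registry has no death cause; any application must code an explicit level
  (e.g. "Other") for all rows, and estimates for that covariate condition
  on eventual cause, which is not a causal quantity.
- Delayed entry, time-varying covariates, competing risks, gamma frailty
  and >2-level hierarchies are out of scope.
- Printed AICs for random-effects survival models differ across software
  conventions (effective degrees of freedom vs parameter counts); this
  package always reports −2·ℓ_int + 2·(k_fixed + 1) and both likelihood
  flavors, so cross-package AIC comparisons should be made on the
  log-likelihoods.
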