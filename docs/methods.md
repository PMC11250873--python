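# Methods

## Outcome and sample definition

The unit of observation is one vehicle in a fatal multivehicle crash.  The
ordinal outcome counts the driver warning systems standard-fitted on the
vehicle, derived from the VIN availability codes of FCWS and BSM: both
"Standard" → 2, exactly one "Standard" with the other "Not Available" → 1,
both "Not Available" → 0.  A code of "Optional" (or a missing code) makes
actual fitment unknowable from the VIN, so such vehicles are excluded
rather than coded as absent.  Rows from single-vehicle crashes are dropped
(the comparison of interest is between vehicles in comparable multivehicle
collisions), and rows missing any model covariate are deleted listwise.
Listwise deletion is defensible only while the missing share is small; the
filter warns above 2%, the level at which the source data's own missingness
sat.  Each removed row is charged to exactly one rule, in the order
single-vehicle → optional code → unknown code → missing covariate, so the
filter report's tallies sum to the number of removed rows.

## Spatial matching

Crash risk is spatially autocorrelated, and vehicles carrying warning
systems are concentrated where the newest fleet drives.  Before modelling,
each case (outcome ≥ 1) is matched to its k nearest controls (outcome 0)
by great-circle distance; the union of cases and deduplicated controls is
the analysis sample.  Distances use the haversine formula with an Earth
radius of 20,902,231 ft; neighbor search is exact (a ball tree, not an
approximate index), and ties are broken by pool order so matching is
deterministic.  k defaults to 3; since the criterion by which an optimal k
should be chosen is application-specific, `k_profile` reports the worst
k-th-neighbor distance across k for manual inspection.  Controls are
selected with replacement across cases and deduplicated, so a control
shared by two cases enters once.

## Temporal coding

Year enters as the linear index year − 2015 ∈ {1..5} rather than as
dummies, estimating a single linear-in-time trend on the latent scale.

## Ordered logit parameterization

The latent propensity Y* = β'X + ε with standard-logistic ε is cut at
(−∞, 0, ψ₁, ∞).  With three categories only one threshold is free once an
intercept is estimated; fixing the first threshold at zero and reporting
ψ₁ > 0 (optimized as exp δ) is the identification used throughout, and ψ₁
carries a delta-method standard error.  Estimation is BFGS with the
analytic score, then Newton polishing with a finite-difference Hessian of
the score; convergence requires a gradient infinity-norm below 1e-6
(the likelihood is smooth and the polish step reaches this reliably).
Reference levels for the dummy coding are Summer, 6–9 a.m., Angle
collision, two lanes, dry surface, tracking, principal arterial, daylight,
clear weather, male, age 24–40 and rural; all are overridable.  The design
condition number is reported as a multicollinearity diagnostic, but no
columns are dropped automatically.

## Correlated random parameters

The five driver-behaviour columns (drink-driving, female, and the three
non-reference age bands) receive normally distributed random coefficients
βᵢ = β + Ωφᵢ with an *unrestricted* lower-triangular Ω, so the implied
covariance ΩΩ′ is positive semidefinite by construction and off-diagonal
elements capture correlation between behavioural effects.  Only the normal
mixing distribution is implemented, and neither means nor variances shift
with covariates.

The per-observation likelihood integrates the ordered-logit probability
over φ; the integral is simulated as the mean over D Halton draws.  Draw
configuration: dimension d uses the d-th smallest prime (2, 3, 5, 7, 11);
the first 10 sequence elements are discarded (the leading radical inverses
are degenerate); observation i takes the i-th consecutive block of D
elements, mapped through the standard-normal quantile.  All three choices
are conventional for simulated likelihood and configurable.  D defaults to
900, the draw count at which this model family's estimates are reported to
stabilize; the simulated log-likelihood at Ω = 0 equals the fixed-model
log-likelihood exactly for any D, which is both a correctness oracle and
the basis of the nested comparison.

Ω is optimized unconstrained (better-behaved than positivity transforms)
starting from the fixed-model fit with Ω₀ = 0.1·I; afterwards any column
with a negative diagonal element is negated, together with the matching
draw dimension, so the reported diagonal is nonnegative and the reported
log-likelihood is exactly unchanged.  Standard errors come from the inverse
numerical Hessian of the simulated log-likelihood (central differences of
the analytic score); simulated probabilities are floored at 1e-300 before
the log, and floored observations are counted and flagged.  The default
gradient tolerance is 1e-5; the simulated surface is flatter than the fixed
one, so nonconvergence is reported with the gradient norm rather than
hidden.

## Marginal effects and model comparison

For indicator v, the effect on category k is
P(Y = k | X̄, v = 1) − P(Y = k | X̄, v = 0) with all other covariates at
sample means; the year index uses a +1 increment from its mean.  For the
correlated model the probabilities are draw-averages over the fitted mixing
distribution, using one fixed Halton block per effects table so that
finite-difference gradients over the parameters are smooth.  Effects across
the three categories sum to zero (probability conservation) — verified to
1e-3 on every fitted model.  P-values are delta-method; an
observation-averaged variant (`at="observations"`) is provided for
sensitivity analysis.  McFadden pseudo-R² is 1 − LL/LL₀ with an
intercept-plus-threshold-only null.  The likelihood-ratio statistic
2(LL_crp − LL_fixed) is referred to chi-square with one degree of freedom
per free Cholesky element; because the null pins the variance parameters at
the boundary of the parameter space this reference is conservative (it
under-rejects), which is the safe direction for claiming heterogeneity.

## Synthetic generator

The generator draws covariate categories independently per variable from
the published marginal shares (only marginals are published; an optional
two-variable dependency hook exists for sensitivity scenarios), coordinates
from a six-cluster Gaussian mixture weighted toward the U.S. east coast,
years with rising shares (0.10/0.14/0.18/0.24/0.34 for 2016–2020, echoing
the growth of warning-system fitment), integer driver ages uniform within
their band, and 2–4 vehicles per crash.  The outcome comes from the exact
correlated random-parameters process with, by default, the published
estimates as generating truth (constant −3.898, year 0.584, the published
random means, Cholesky factor and ψ₁ = 1.644).  Generation uses seeded
pseudo-random draws — never Halton sequences — so estimation draws and
generation draws cannot coincide.  Contamination (missing covariates,
"Optional" codes, single-vehicle rows) is injected on disjoint row sets so
the filter report must match the injected counts exactly.

What the generator does **not** emulate: covariate dependence beyond
marginals, real road-network geography, within-crash correlation between
the vehicles of one crash, and any spatial or temporal structure in the
*outcome* beyond what the year trend and covariates induce.  Passing tests
therefore demonstrate correctness of the estimators under the stated
generating process, not robustness to the dependence structures of real
crash data.

The compact recovery scenario keeps the five-dimensional random block but
only five fixed columns, with a milder constant (−1.0) and year trend
(0.25) chosen so all three outcome categories stay well populated — random
covariance parameters are weakly identified when a category nearly empties.

## Problem sizes and tolerances

The shipped experiments run at sizes a laptop handles comfortably: the
recovery experiment uses 20 replicates at n = 5000 with D = 200 (the full
study design is n ≈ 8757, D = 900); unit-test fits use n = 300–1200 with
D = 25–100; the acceptance script's end-to-end study runs at the published
n with D = 200.  Independent cross-checks: the fixed MLE agrees with
statsmodels' ordered-logit to < 1e-6 relative log-likelihood and < 1e-4 in
coefficients; the simulated likelihood with one random coefficient agrees
with 50-node Gauss–Hermite quadrature to < 1e-3 per observation; neighbor
matching agrees exactly with exhaustive search.

## Known limitations

- The unit of observation is the vehicle; crashes contributing two
  analysis vehicles appear twice with no within-crash dependence modelled.
- Listwise deletion assumes missingness at random below the 2% warning level.
- Delta-method p-values for effects and the chi-square LR reference are
  asymptotic; the boundary issue of the LR test is documented above.
- Random-coefficient covariance diagonals are weakly identified for rare
  indicators (e.g. drink-driving at ~10% prevalence); their sampling
  uncertainty at n = 5000 is large, which the recovery report's standard
  errors make explicit.
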