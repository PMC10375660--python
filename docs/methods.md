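# Methods

This note records the package's statistical model, the estimation
algorithm, the assumptions baked into the synthetic generator, and the
numerical choices a maintainer would otherwise have to reverse-engineer.
It states no empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## 1. Flight kinematics

All directions are geographic degrees clockwise from true North; wind is
held internally in the *blowing-towards* convention ("from"-convention
station files are rotated by +180 on read, and every reader carries an
explicit convention flag). Angle differences are wrapped to (-180, 180].

Positions are WGS84 lon/lat. Bearings and distances over the <= 60 km
radar range use a local tangent plane with per-latitude degree lengths
from the meridional and prime-vertical radii of curvature; the error of
this approximation (< 0.01% at these ranges) is far below the radar's own
positional accuracy (+-90-200 m). A spherical great-circle mode
(`mode="geodesic"`, mean radius 6371.0088 km) exists for cross-checks;
the two modes use different earth models and agree to ~0.3% — the tests
encode exactly that.

Per track: groundspeed `V_g` = endpoint distance / duration and track
angle `theta_b` = initial bearing (endpoint computation is the default
even when a radar-reported speed column exists; that column is retained);
airspeed `V_a` = |ground vector - wind vector|; tailwind
`W_t = W cos(theta_w - theta_m)` and crosswind
`W_c = W sin(theta_m - theta_w)`, signed so that an *eastward* wind
against a southward goal direction is a *positive* crosswind (pushing the
bird's left; `left_positive=False` flips); sideways speed
`V_s = V_a sin(theta_b - theta_m)` using the TRACK angle. A heading-based
variant (`lateral_component_heading_based`) measuring the air vector's own
lateral component is provided for comparison: the two differ whenever the
bird compensates, and the track-angle form is the package's default
definition. Vertical speed is `V_g sin(theta_s)` with the slope angle from
altitude gain over horizontal distance (atan2). The goal direction
`theta_m` defaults to the circular mean of all track angles in the dataset
(the way a corridor's reference direction of ~187.7 deg arises) and can be
fixed for exact replication.

## 2. Sessions

Tracks are filtered to 3 h after sunrise .. 3 h before sunset (NOAA solar
equations at the radar site, civil zenith 90.833 deg, no refraction
tuning; accuracy ~+-1 min, tested against an independent ephemeris at
+-2 min) within the Aug 16 - Sep 30 season, annotated with the
nearest-in-time wind record (ties to the earlier record; gaps > 30 min
drop the track, counted and logged), then averaged into clock-aligned
15-min sessions: arithmetic means for linear quantities, circular mean
for the track angle, equal weight per track (track durations are nearly
identical, so duration weighting is immaterial). Sessions keep
`n_tracks >= 1`; no minimum is imposed, the count is retained so users can
weight or filter. The time covariate is *hours before sunset* as negative
decimal hours (-6.25 = 6 h 15 min before sunset).

## 3. Circular statistics and wind trends

`circular_summary` gives the resultant length r, circular mean, circular
SD `sqrt(-2 ln r)` and the Rayleigh p-value via the standard large-sample
approximation with the second-order small-n correction; the exact variant
used by other software differs negligibly at these sample sizes.

The diurnal wind-trend models are deliberately simple: wind direction (as
unwrapped radians — the sea-breeze stays within a half-circle per day, so
no full circular regression machinery) and wind speed are fitted per year
as quadratics in hours-before-sunset, with the date-level random intercept
absorbed by within-date centering (two-stage estimation): slopes from the
within-date estimator, intercept from the year's grand means, and the
between-date spread of adjusted date means as the intercept-variance
estimate. Between-year homogeneity is an extra-sum-of-squares F comparing
the pooled within-date fit against per-year fits. This replaces a full
random-slope mixed model; it is a documented simplification, adequate
because the quadratic trend is strong and the design nearly balanced.

## 4. The smoother

The GAMM engine fits

    y_i = alpha + f(x_i) + b_year(i) + e_i

* `f`: natural cubic regression spline with k = 12 basis functions
  (values-at-knots parameterization, knots at quantiles of the unique x;
  k counts columns *before* the identifiability constraint), sum-to-zero
  constraint absorbed by a QR null-space reparameterization, curvature
  penalty `integral f''^2` exact in this parameterization
  (`S = D' B^{-1} D`);
* `b_year`: ridge-penalized dummy block — the standard
  random-effect-as-smooth equivalence — with its own REML-estimated
  precision;
* `e`: AR(2) within each ordinal date, independent across dates,
  position-based (consecutive sessions are unit lags), matching the
  reference correlation structure's behaviour.

Estimation alternates until parameters move < 1e-6 (max 50 outer
iterations, non-convergence flagged and the last iterate returned):

1. whiten y and X within each date by the inverse Cholesky factor of the
   AR(2) correlation matrix at the current (phi1, phi2);
2. choose (log lambda, log tau) by minimizing the profiled -2 restricted
   log-likelihood with L-BFGS-B (bounds +-15/20 on the log scale, explicit
   finite-difference step 1e-5 — the objective's magnitude makes the
   default 1e-8 step indistinguishable from float noise);
3. re-estimate (phi1, phi2) by pooled Yule-Walker on the within-date
   residuals, shrinking toward zero if outside the stationary triangle.

Profiling the AR coefficients via Yule-Walker instead of joint REML is a
robustness choice: the triangle constraint and the near-flat likelihood in
phi make joint quasi-Newton optimization fragile, while Yule-Walker is
closed-form and consistent. Step 2 solves the penalized least squares
through the augmented QR (rows [X; sqrt(P)]), not the normal equations:
at extreme lambda the normal equations lose the unpenalized null-space
component to conditioning (squared condition number), which had trapped
the optimizer on exactly-linear data. The residual sum of squares is
floored at 1e-24 * y'y so that exactly-representable data (RSS ~ 0) leave
the determinant terms in charge — lambda then runs to its bound and the
effective degrees of freedom collapse to the penalty null space (edf -> 1
for the smooth), the correct degenerate behaviour.

The stored coefficient covariance is the Bayesian / prior-inclusive
`V = sigma2 (X'X + P)^{-1}` on the whitened design; simultaneous intervals
are defined on it. The smooth's edf is the trace of the influence-matrix
block over the smooth columns; `1 <= edf_smooth <= k - 1`. On shared data
the whole fit (edf, curve, pointwise SEs) reproduces the reference R
implementation to the tolerances asserted in the tests.

Gaussian identity-link responses only (all responses here are speeds in
m/s); no MA components; one smooth term. Fit objects serialize to JSON so
derivative inference can run on stored fits.

## 5. Derivative inference

`f'(x)` is evaluated on N = 1000 grid points spanning exactly the observed
covariate range (no extrapolation) by forward finite differences of the
predicted curve with eps = 1e-7; at the upper endpoint the step is taken
inward. Central differences and the exact basis-derivative linear
functional are also available; the finite-difference and exact routes
agree to 1e-4 relative (asserted over random fits), and eps below 1e-9
triggers a cancellation warning.

The 95% simultaneous band draws n_sim = 10,000 coefficient vectors from
N(beta_hat, V), forms each draw's derivative curve (in chunks, so memory
stays ~10 MB), and takes the 0.95 quantile m* of the max over the grid of
|deviation|/SE; the band is f' +- m* SE, two-sided on the standardized
max-abs statistic. A singular V falls back to an eigenvalue pseudo-root
with a warning; V -> 0 collapses the band onto the point estimate.
Significant increase/decrease periods are maximal runs of grid points with
lower bound > 0 or upper bound < 0, reported at grid resolution.

Calibration: the band's whole-curve coverage is nominal (measured 95.4%
over 500 replicates of the nested 7x20x28 AR(2) world) when the true curve
lies in the spline space. For truths outside the basis (e.g. a sinusoid
across 7 radians with k = 12) coverage erodes at large n because basis
approximation bias does not shrink with the SEs — a fixed-k caveat users
should know when dating change periods from very large datasets.

## 6. The synthetic world

`WindScenario` emulates the Levant-coast autumn sea-breeze: mean direction
rotating clockwise 87.1 -> 131.1 deg (the observed morning/afternoon
means) by shortest-arc linear interpolation over the -10..-3 h window
(180-deg ties broken clockwise, matching the rotation's sense), speed
following a quadratic in hours-before-sunset through ~1.5 m/s at -10 h,
the observed 4.1 m/s mid-window and ~5.2 m/s at -3 h, Gaussian noise
(direction sd 25 deg, speed sd 0.8 m/s, chosen inside the observed +-39.5
and +-1.1 spreads since part of those is the diurnal trend itself), speeds
clipped at zero, records every 10 min.

`BirdScenario` encodes the behavioural rules the analysis looks for:
goal direction 187.7 deg; airspeed = 16.5 - 0.6 * tailwind m/s (slope
chosen so a ~3.5 m/s tailwind gain over the day yields the observed
~2 m/s airspeed drop); heading from the compensation mode (full: the
ground vector points at the goal; drift: heading = goal; partial: convex
combination of the two heading angles); required airspeeds above a 30 m/s
cap are truncated with a warning and flag. Session-level AR(2) noise
(phi = (0.5, 0.2), marginal sd 0.4 m/s, innovations scaled accordingly,
reset at day boundaries) perturbs the airspeed *base*, after which the
triangle is re-solved — so every emitted session satisfies
air + wind = ground exactly and the analysis kinematics recover the
emitted quantities to machine precision. Track directions scatter around
the session truth as von Mises draws (kappa = 200, ~4 deg sd; `None`
disables scatter). Ground-truth expectations are emitted as `true_*`
columns so recovery tests never reach into generator internals. One
global seed expands through `SeedSequence(entropy, spawn_key=(year, day))`
substreams, making each day independently reproducible. Default sizes:
7 years x 20 days x 28 sessions x 20 tracks. Residuals are Gaussian (no
distributional family is implied by the data; Gaussian is consistent with
the GAMM).

`flat_then_decline_scenario()` is the named change-detection testbed: wind
starting perpendicular to the goal with near-zero speed so the expected
airspeed is flat (|rate| < 0.06 m/s/h) before -8 h, then declining at
0.35-0.57 m/s/h over the last two hours.

What the generator does *not* emulate — and what a green test therefore
does not establish: thermals/updrafts and the sea-breeze front's vertical
circulation, altitude-dependent winds, species mixtures, radar detection
biases, within-track position error, and irregular session spacing (the
paper's 6.25% 30-min gaps). Sessions are kinematically self-consistent by
construction, which real session means (averages over heterogeneous birds)
are not.

## 7. Other numerical choices

* Nearest-wind ties: earlier record; wind gap cap 30 min (10-min series).
* Aggregation bins: clock-aligned 15-min floors when no radar session
  markers exist; interval configurable (30-min sessions tolerated).
* Circular means that round to 360.0 by float error are reported as 0.0.
* Zero-displacement tracks get V_g = 0 and a flagged undefined angle;
  zero-duration tracks are an error.
* The pipeline manifest hashes only text artifacts (CSV/JSON), so a
  same-seed rerun is verifiable byte-for-byte; the PNG diagnostic is
  excluded from hashing.
* All randomness flows from explicit seeds; the CLI requires one for the
  posterior simulation and logs it in the output.

## 8. Known limitations

* One smooth term, Gaussian responses, AR order <= 2, no MA part, no
  tensor smooths — exactly the scope the analysis needs and no more.
* The wind-trend "mixed model" is a two-stage approximation (above).
* The Rayleigh p-value is an approximation; at n in the thousands this is
  irrelevant, at n < 10 use caution.
* Simultaneous bands inherit the fixed-k caveat of Section 5.
* The AR correlation is position-based within a date; if sessions are
  irregularly spaced in time the implied correlation is by order, not by
  elapsed time (faithful to the reference implementation's behaviour).
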