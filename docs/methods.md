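# Methods

This note documents the statistical model, the numerical choices, the
synthetic-data generator that underpins all tests, and the known
limitations of the package.

## Model

Movement is summarised per hourly step as a (step length, turning angle)
pair.  Step length is the Euclidean distance between consecutive
positions in a projected metre coordinate system; the turning angle is
the signed heading change between consecutive displacements, wrapped to
(-pi, pi], counter-clockwise positive.  (The sign convention has to be
fixed somewhere: von Mises symmetry makes results invariant as long as
it is applied consistently, and this package always reports
counter-clockwise-positive angles.)

Conditional on a K-state latent Markov chain, steps are gamma with a
mean/sd parameterisation (shape = mu^2/sigma^2, rate = mu/sigma^2),
optionally zero-inflated with a point mass zeta at exact zeros, and
angles are von Mises(phi, kappa).  A missing step or angle contributes
an emission factor of 1, so gaps propagate the chain without
information.  Transition probabilities follow a multinomial logit in
per-step covariates with the self-transition as reference category; the
coefficient matrix has one row per design column (intercept first) and
K(K-1) columns ordered row-major over ordered state pairs.

The initial state distribution is a free parameter vector shared across
bursts (the transition matrix is time-varying under covariates, so a
stationarity assumption at burst starts would be arbitrary).  A
configurable alternative (`stationary_start=True`) instead uses the
stationary distribution of Gamma at each burst's first design row; in
that mode the analytic gradient ignores the (weak, O(number of bursts))
dependence of the initial distribution on the transition coefficients.

## Estimation

The scaled forward recursion gives the exact log-likelihood; bursts
multiply.  Optimisation runs on an unconstrained working scale: log for
mu, sigma, kappa; logit for zeta; the angle mean is estimated directly
and wrapped into (-pi, pi] afterwards (simpler than the paired
kappa*sin/kappa*cos parameterisation and empirically stable under
multi-start); the initial distribution uses a multinomial logit against
state 1; transition coefficients are unconstrained.

The zero mass zeta is estimated only when the data contain exact zeros;
otherwise it is fixed at 0 and excluded from the parameter count used by
BIC.  The BIC sample size is the number of non-missing step
observations.

The optimiser is L-BFGS with an *analytic* gradient obtained from the
forward-backward adjoint: smoothed state posteriors weight the
per-observation emission score functions, and transition-pair adjoints
(xi_t(i,j) - gamma_t(i) Gamma_ij(t)) chain through the design matrix
into the logit coefficients.  Each start is run to a relative function
tolerance of 1e-10 and then restarted once with fresh curvature memory:
L-BFGS on these likelihood surfaces occasionally declares convergence on
a plateau that a restart escapes.  Thirty random starts are the default;
starting values draw ordered step means log-uniformly between the 10th
and 90th percentile of observed positive steps (sd = mean), log-uniform
concentrations in [0.1, 5], angle means from {0, pi}, sticky transition
intercepts Normal(-2, 0.5^2) and zero covariate slopes.  After fitting,
states are relabelled by ascending step mean so that state 1 is resting,
2 foraging, 3 relocating, and the label convention holds everywhere
downstream (decoding, curves, budgets).

Because the continuous gamma / von Mises likelihood is unbounded when a
state degenerates onto single observations (sigma -> 0 with shape -> inf,
or kappa -> inf), the objective rejects parameter points with gamma shape
above 1e6 or concentration above 1e4 — far beyond anything biologically
meaningful.  Model-selection fits additionally include a deterministic
moment-based start (step quantile groups seed the state means) alongside
the random ones, since BIC comparisons are only as reliable as each
fit's optimum.

The estimator covariance is the inverse observed information, with the
Hessian computed by central differences of the analytic gradient at the
optimum.  The forward/backward/Viterbi recursions are numba-compiled;
all numerics are float64.

## Model building and inference

Forward BIC selection adds candidate covariates in blocks (sin/cos pair
for cyclic, dummy set for categorical, single column for continuous) to
all K(K-1) transition predictors simultaneously, starting from the
intercept-only model, adopting the best block per round while BIC
improves.  Ties are broken by declared block order.  Selection-round
fits run in a reduced-cost mode (5 starts by default, one of which
warm-starts from the incumbent model with zero slopes for the new
block); the base intercept-only fit gets at least 8 starts because every
later comparison is anchored to it, and the final model is refitted at
full strength (30 starts) with the Hessian.  State numbers K = 2..5 are
compared by a reported (K, logL, k, BIC) table with no automatic choice:
on real movement data BIC tends to favour ever-larger K, and K is a
scientific, not purely statistical, decision.

Stationary state-occupancy curves fix all other continuous covariates at
their seasonal means (the encoder's centring constants, computed over
all non-missing fix-level values in the fitted data), categorical
covariates at their reference levels, cyclic covariates at explicit
context values (e.g. hour 12), and solve delta Gamma(x) = delta per grid
value via the augmented linear system.  Treating a time-varying chain
through per-x stationary distributions is an approximation: it describes
the long-run occupancy *if* covariates froze at x, not the realised
time-varying occupancy.  Confidence bands draw parameter vectors from
the estimator's approximate multivariate normal, marginalised to the
transition-coefficient block the curve actually depends on (the
coefficients are unconstrained, so working and natural scale coincide;
marginalising keeps weakly identified nuisance blocks such as the
initial distribution from contaminating the draws), recompute the curve
per draw and take pointwise 2.5/97.5 percentiles (1000 draws by
default; the rare draw whose transition matrix has no unique stationary
law is dropped).  A non-PSD covariance is repaired by clipping negative
eigenvalues, with a warning.

Pseudo-residuals are one-step-ahead probability integral transforms:
the forecast CDF of each observation given all earlier observations of
its burst, mixed over states with the forward prediction weights, mapped
through the standard normal quantile.  The von Mises CDF uses a Bessel
series anchored at -pi.  The discrete atom at a zero step is assigned
its mid-probability.  CDF values are clamped to [1e-12, 1 - 1e-12] with
a warning before the normal quantile.

## Preprocessing rules

* Bursts: tracks are split where more than 10 consecutive hourly
  positions are missing (a gap's length is the number of missing grid
  hours); shorter gaps stay as missing positions on the grid.
* Seasons: "snow encounter" is snow depth > 0 at the fix (threshold
  configurable).  The interval from the start of the first 48-h
  snow-free run to the end of the last one is summer; everything else
  winter; bursts are cut at the boundaries.
* Seasonal bursts shorter than 4 full weeks (672 hourly slots) are
  dropped, with a removal report.
* Missing continuous covariates are linearly interpolated on the hourly
  grid (edges padded with the nearest value); categorical covariates
  take the nearest non-missing neighbour, earlier on ties.
* Covariate collinearity is screened by pairwise Pearson correlation
  with |r| >= 0.6 flagged.
* An optional speed screen flags fixes implying sustained speeds above
  2.5 m/s; it is off by default since impossible-movement screening is
  normally done upstream of this package.
* Dynamic covariate grids are sampled at the grid time nearest the fix,
  earlier slice on ties; fixes outside a raster's extent yield missing
  values (later interpolated).  Rasters are planar numpy grids with
  ESRI ASCII text I/O; the terrain ruggedness index is the mean absolute
  elevation difference between a cell and its 8 neighbours (edge cells
  use the neighbours they have — a checkerboard therefore has interior
  TRI 0.5, since the 4 diagonal neighbours are equal).
* Daylight/darkness comes from the NOAA low-accuracy solar position
  algorithm with the conventional -0.833 degree sunrise elevation; polar
  day and night fall out naturally.  Light seasons label each date as
  midnight sun (no sunset), polar night (no sunrise), or
  increasing/decreasing light split at the summer solstice.
* Timestamps are UTC throughout; the hour-of-day covariate is the UTC
  hour by default with a configurable local-solar offset.

## Synthetic data generator

The generator is first-class, tested code: it defines the study
conditions for every downstream validation.  It emulates hourly
arctic-ungulate telemetry — regular sampling with occasional multi-hour
fix gaps, three latent states with distinct gamma/von Mises emissions,
transition probabilities modulated by a diel cycle and by slowly varying
covariates, and a high-latitude light schedule — while deliberately
omitting spatially explicit covariate fields, snow physics, GPS
measurement error and social interaction.  Passing tests therefore
demonstrate correctness of the estimation machinery under the model's
own assumptions, not robustness to the ways real tracks violate them.

Canonical defaults (all chosen once, on realism grounds, documented
here):

* Emissions: resting mu = 20 m, sigma = 15 m, phi = pi, kappa = 1.0
  (weakly concentrated, 180-degree biased, mimicking GPS jitter around a
  stationary animal); foraging mu = 180 m, sigma = 110 m, phi = 0,
  kappa = 0.7 (tortuous grazing movement; the mean sits inside the
  96-348 m/h band implied by published muskox grazing speeds of
  1.6-5.8 m/min); relocating mu = 600 m, sigma = 350 m, phi = 0,
  kappa = 4 (directed travel).  The resting concentration is 1.0 rather
  than something closer to uniform because the recovery benchmark
  requires well-separated, identifiable emissions: below kappa ~ 0.5 the
  sampling error of the maximum-likelihood estimate at ~7,500 resting
  steps exceeds the 5% recovery tolerance the benchmark checks, and the
  benchmark would measure sampling noise instead of estimator
  correctness.
* Transitions: sticky intercepts (-2 on all six off-diagonal pairs), a
  diel sin/cos effect on the resting/foraging switches, and a
  standardised snow-depth effect pushing the chain toward resting
  (+0.8 into resting, negative on leaving it) — the qualitative
  winter-constraint pattern the model family is designed to detect.
* Covariates: temperature is an exactly 24 h-periodic sinusoid
  (mean -15 C, amplitude 4 C, peak at 14:00); snow depth is stationary
  AR(1) with mean 0.35 m, sd 0.12 m, lag-1 autocorrelation 0.98; wind
  speed AR(1) with mean 5 m/s, sd 2 m/s, rho 0.9; landcover is a sticky
  3-level categorical chain (stay probability 0.95); light follows the
  solar schedule at 74.5 N, 21 W.
* The canonical recovery scenario uses 5 animals x 5001 hours = 25,000
  steps in 5 bursts, with the transition design standardised by the snow
  *process* mean/sd so generative coefficients are exactly comparable to
  refitted ones.
* Position integration starts each track at the origin with a uniform
  random initial heading; a zero step (when configured) keeps the
  heading and blanks the adjacent turning angles, exactly matching the
  preprocessing convention, so steps/angles recomputed from simulated
  positions reproduce the generator's draws to floating-point accuracy.

## Validation studies and problem sizes

The acceptance suite (and `scripts/acceptance.py`) runs six studies,
sized to complete comfortably on one CPU:

1. Forward likelihood and Viterbi against exhaustive path enumeration:
   200 random parameterisations, K in {2,3}, T in 2..8, including missing
   observations and zero-inflated steps; agreement to 1e-8 / exact.
2. Stationary solver: 1000 random ergodic 3-state matrices; residual
   below 1e-12 and power-iteration agreement to 1e-8.
3. Full-pipeline parameter recovery on the canonical 25,000-step
   scenario with 30 starts: emissions within 5% relative error (angle
   means within 0.05 rad on the circle, two true means being zero),
   transition coefficients within a joint 3-sigma Mahalanobis region
   under the estimator covariance (a max over 24 marginal z-scores would
   reject ~6% of correct fits by chance), decoding accuracy above 90%.
4. Forward-selection sanity: 20 replicates of ~2500 steps with snow
   depth the only active covariate among five candidate blocks; the
   active block must be adopted first and selection stop, in >= 90% of
   replicates.
5. Confidence-band calibration: 100 replicates of 800 steps under the
   snow-only transition design (the smallest model with a non-trivial
   curve), 95% pointwise bands on the snow stationary curve; coverage of
   the generative curve within Monte Carlo slack of nominal.  Replicates
   whose fit does not reach an interior optimum (non-positive-definite
   observed information — the band method's stated precondition) count
   as fit failures rather than misses; Wald-type bands at this size
   still undercover mildly (a well-known small-sample effect), which the
   slack accommodates.
6. The preprocessing boundary rules (10 vs 11 h gaps, 671 vs 672 h
   bursts, 47 vs 48 h snow-free runs), exact.

Replicate counts and per-replicate sizes for studies 4 and 5 are
scaled-down versions of study 3's conditions, chosen so the whole suite
stays fast while each check retains adequate statistical resolution.

## Limitations

* No individual random effects or hierarchical structure: all animals
  share one parameter set per season, as in the modelling tradition this
  package follows.
* The stationary occupancy curves are a long-run approximation under a
  frozen covariate value.
* Pseudo-residual normality is asymptotic and approximate at burst
  starts.
* The impossible-movement screen is a simple sustained-speed flag, a
  stand-in for dedicated telemetry cleaning tools.
* Planar coordinates are assumed; geographic (lon/lat) input is detected
  heuristically and rejected rather than reprojected.
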