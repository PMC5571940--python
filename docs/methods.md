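# Methods

## The model

`beetlekern` estimates how far pollen beetles (*Brassicogethes aeneus*)
disperse in spring from their woodland overwintering sites into winter
oilseed rape (OSR) fields, from count data alone.  The observation at
sampling point *i* and weekly date *t* is the number of beetles on ten
plants, modelled as negative binomial,

    y(t, i) ~ NB(mu(t, i), theta),        Var = mu + mu^2 / theta,

with mean

    mu(t, i) = gamma_g * sum_w gamma_d(d_iw, delta(t)) * A_w .

The sum runs over woodland *source pixels* w within 5 km of the point:
woodland polygons are discretized on a 100 m grid and each pixel carries
the wooded area A_w it covers, optionally split into the 100 m-wide
peripheral band ("edge") and the deeper "core" so that edge-only
emergence can be tested.  gamma_d is a two-dimensional dispersal kernel,

    gamma_d(d, delta) = exp(-(d / delta)^n) / (K * pi * delta^2),

gaussian (K=1, n=2) or exponential (K=2, n=1), both integrating to one
over the plane.  The distance scale changes linearly with the weekly
date index,

    delta(t) = beta_d + beta_dt * (t - 1),   beta_d > 0, delta(t) > 0,

and the mean radial dispersal distance is D_mean = 2*delta
(exponential) or sqrt(pi)/2 * delta (gaussian).  A configuration switch
`delta_convention="inverse"` reads the linear form as the reciprocal
scale instead; the default ("scale") is the convention under which the
closed-form D_mean expressions and the sign of fitted time trends are
mutually consistent, and it is the one used throughout.

gamma_g = exp(coef) is a categorical *size factor* absorbing
date-to-date visibility/emergence changes and field- or site-level
heterogeneity.  Eight designs are supported: "1", date, field, site,
field+date, site+date, field:date, site:date (term order immaterial).
Additive designs keep every level of the first factor free and fix the
first level of each further factor to zero.  One amplitude must remain
free because the kernel sum has no free scale of its own; a
parameterization that zeroes the reference level of *both* factors
would pin gamma_g = 1 at the reference cell and make the model unable
to fit the overall abundance level.

Priors: Cauchy(0, 2.5) on each size-factor coefficient (log scale) —
the standard weakly-informative choice for positive multiplicative
effects; flat on log(theta); flat on (beta_d, beta_dt) inside their
definition domain.  Internal computations use km and km²; the I/O layer
works in meters and converts once at load.

## Model space

The factorial modality grid crosses the size-factor design, the source
origin (whole area vs edge band), the point structure (split = actual
point coordinates, merged = field barycenter, none = no geometry), the
kernel family, and whether (beta_d, beta_dt) are fitted separately per
site.  "none" makes origin/kernel/site-dependence meaningless, so the
cross product collapses there to one spec per size factor; the full
default grid has 8*2*2*2*2 + 8 = 136 distinct models.  Models are
ranked by AIC = 2k - 2 log L_max; k counts the free size-factor
coefficients, the dispersal parameters (two per site group) and
log(theta).

## Inference

Each model is fitted by component-wise random-walk Metropolis.
Proposal scales adapt toward an acceptance rate of 0.44 (the
one-dimensional optimum) during the first block and are then frozen;
the first block is discarded as burn-in.  Sampling proceeds in blocks
until, for every parameter, the Geweke stationarity z-score (first 10%
vs last 50% of the chain, spectral variance by Bartlett/Newey-West
window) satisfies |z| < 1.96 *and* the chain is at least as long as the
Raftery-Lewis run length required to estimate the 2.5% quantile to
±0.005 with probability 0.95; or until a block budget is exhausted, in
which case the fit is flagged non-converged but still usable, so large
model sweeps always complete.

Point estimates follow a maximum-likelihood-in-chain rule: the sampled
vector with the highest likelihood, unless the vector of per-parameter
medians evaluates strictly higher, in which case the medians are
reported (the choice is recorded).  Intervals are the 2.5%/97.5%
empirical quantiles with linear ("type 7") interpolation.  The
likelihood entering AIC is this chain maximum; it understates the true
maximum slightly, a known and documented limitation shared by all
models in a comparison.

### Numerical acceleration

The sampler evaluates the likelihood ~10^5–10^6 times per fit.  Two
devices keep this cheap without changing the model:

* the per-point kernel sum S_u(delta) = sum_w A_w gamma_d(d_uw, delta)
  is precomputed on a 160-knot log-spaced grid of delta in [0.02, 60] km
  (log-stable via logsumexp) and interpolated during sampling by a
  cubic spline of log S against log delta, with linear continuation
  beyond the grid where log S is asymptotically linear (slope -2 at
  large delta).  Interpolation error in log S is ~1e-6; the test suite
  cross-checks the spline likelihood against the plain quadratic-cost
  reference implementation (`dispersal.log_posterior`) at random
  parameter vectors;
* the Metropolis sweep itself is compiled with numba, maintaining the
  linear predictor and kernel-sum state incrementally per component
  update.

The synthetic-data generator deliberately uses the exact (non-spline)
forward model, so generator and sampler do not share the approximation.

## Baseline buffer regression

The conventional landscape-ecology baseline relates counts to the
woodland area A_BW in a disk around each point:
log mu = beta_G(level) + log A_BW, a negative-binomial GLM with
canonical log link and unit-coefficient offset.  For fixed theta the
coefficients are fitted by IRLS (statsmodels GLM); theta is profiled by
bounded scalar search of the likelihood.  Observations with A_BW = 0
enter through the exact mu -> 0 limit (log-probability 0 for count 0,
-inf otherwise) — no epsilon floor.  The radius is scanned from 0.2 to
5 km in 200 m steps, ties toward the smallest radius.  The size-factor
design defaults to site:date and is configurable; by default the whole
wooded area (edge + core) counts toward A_BW.

## Synthetic data

The generator emulates the study conditions the analysis assumes:

* four sites of 4 x 6 km, 30 km apart, with woodland cover fractions
  (14.2, 23.8, 29.1, 33.1)% forming a simple-to-complex gradient;
  woodland is placed as rectangular patches with median width ~1 km
  (lognormal), i.e. a few large blocks plus smaller woods per site,
  until the realized cover is within 10% of target;
* 6 OSR fields per site (24 total), each sampled at 5 aligned points
  50 m apart on a transect that runs from the woodland-facing field
  edge toward the field middle; field centers are stratified over
  distance-to-wood bands (0.15–0.8, 0.8–1.8, >1.8 km, cycled) so each
  site samples the whole abundance gradient, as transect-based designs
  do;
* 4 weekly dates; counts drawn NB(mu, theta) with mu from the exact
  forward model.

All randomness flows from one master seed through named numpy
sub-streams.

Two truth presets are used by the calibration studies:

* **baseline** — gaussian kernel, beta_d = 1.35 km, beta_dt = 0,
  theta = 1, date-level coefficients spanning the observed dynamic
  range (a rainy-week dip at t2, a flowering peak at t3).  D_mean is
  ~1.2 km, the scale at which the whole analysis operates.
* **field-effect** (model-recovery studies) — field+date coefficients
  (field sd 0.6), gaussian, beta_d = 0.35 km, beta_dt = 0.1 km/week,
  theta = 5.  The shorter, widening scale is a deliberate
  identifiability choice: with the baseline scale the gaussian and
  exponential kernels are statistically indistinguishable at this
  design size (their AIC difference stays below one unit, as is common
  for smooth isotropic kernels matched at the dominant sampling
  distances), so a model-recovery experiment would be a coin flip
  between them.  A scale
  comparable to the transect length makes the kernel shape, the
  split-vs-merged contrast and the distance-by-date interaction all
  carry signal, which is what a recovery experiment is meant to probe.

What the generator does **not** emulate: weather and phenology
covariates, insecticide use, within-field aggregation beyond the
kernel gradient, anisotropic (wind-driven) dispersal, hedgerows and
grasslands as secondary sources, and irregular field shapes.  Passing
recovery tests therefore demonstrate that the estimator works when the
model is true at realistic sizes and noise levels — not that the model
is true of any real landscape.

## Calibration studies (what the tests and the acceptance script run)

* kernel quadrature: total mass and mean radial distance of both
  kernels vs the closed forms, to 1e-6;
* diagnostics: Geweke pass rate on 200 iid chains of 10 000 (nominal
  ~95%); Raftery-Lewis minimum run length for (0.025, 0.005, 0.95),
  closed form 3746, and iid dependence factor ~1;
* parameter recovery: 20 replicate studies under the baseline truth,
  refitting the generating spec with up to 4 blocks of 5000
  iterations; reported are the 95%-interval coverage of beta_d and the
  fraction of posterior medians within 25% of truth;
* model recovery: 20 replicates under the field-effect truth, fitting
  the 10-spec restricted grid {date+field, date:site} x {gaussian,
  exponential} x {split, merged, none} (origin area, site-independent;
  3 blocks of 2500 iterations per fit) and ranking by AIC;
* buffer scan: 20 replicates under the baseline truth; the selected
  radius should be interior to the 0.2–5 km grid (it lands around
  1.4–2.4 km), and rescaling all areas by c must shift every
  coefficient by exactly -log c.

Problem sizes (20 replicates, 15 000–20 000 iterations for recovery
fits, 7 500 for sweep fits) are chosen so the full battery runs in
minutes on one core while leaving the binomial acceptance margins
comfortable.

## Degenerate inputs and tie-breaks

* A sampling point with no source pixel within the cutoff has mu = 0:
  probability one at count 0, impossible for positive counts (model
  compilation rejects data that a spec makes impossible);
* empty woodland rasters, empty polygon sets and zero-area pixels are
  representable and propagate as empty sums;
* the Geweke diagnostic is undefined on (near-)constant series and says
  so; stuck parameters therefore read as non-converged;
* buffer-scan likelihood ties break toward the smallest radius; the
  AIC ranking sort is stable.

## Known limitations

* The chain-maximum likelihood in AIC is biased low by a few units for
  high-dimensional models; comparisons remain fair because every model
  suffers it, but absolute AICs are not MLE-grade.
* Distances are measured to pixel centers, consistent with lumping a
  pixel's area at its center; at 100 m resolution the discretization
  error is negligible relative to kernel scales of hundreds of meters.
* The edge/core split is purely geometric (vector-side erosion by
  100 m); ecological edge effects of other widths require re-running
  the rasterization.
* Site-dependent dispersal multiplies the beta block by the number of
  sites; with few fields per site those posteriors are wide.
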