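# Methods notes

This note records the statistical models, the numerical choices, and the
limits of what the synthetic studies can demonstrate.

## The SCR likelihood

Activity centres form an inhomogeneous Poisson point process over the
habitat mask with intensity `D(s) = exp(θ₀ + Σ θ_d x_d(s))` in animals/km².
Counts of individual *i* at detector *k* over the session are Poisson with
mean

    μ_k(s) = effort_k · λ₀_k · exp(−d(s,k)² / (2 σ_k²)),

where `log λ₀ = φ₀ + Σ φ_l x_l` (per day, at distance zero) and
`log σ = β₀ + Σ β_i x_i` (meters) are detector-covariate models.
Marginalising the unknown centres gives

    −log L = Λ − Σ_i log( Σ_s D(s)·a·Π_k Pois(y_ik; μ_k(s)) )
             + Σ_ik log(y_ik!) + log(n!),

with `Λ = Σ_s D(s)·a·p·(s)`, `p·(s) = 1 − exp(−Σ_k μ_k(s))`, and `a` the
pixel area (km²). The `log(n!)` constant is included (exchangeable-history
convention); it shifts all log-likelihoods by the same amount for fixed
data and cancels in AIC comparisons. Treating the whole session as one
Poisson exposure (`effort_k` days) is exactly equivalent to summing
per-day Poisson occasions, so no occasion structure is modelled; this also
assumes population closure and no temporal variation in detection.

**Units.** The density intercept is log animals/km²; surfaces are reported
per 100 km², the conventional reporting unit for large carnivores. σ is in
meters, λ₀ in encounters/day.

**Standardization.** Mask covariates are z-scored over mask pixels, numeric
detector covariates over detectors, so slopes are per-SD effects.
Quadratic terms square the standardized covariate. `standardize=False`
fits raw covariates; the maximized likelihood and the fitted surface are
invariant to affine covariate changes (tested), only coefficients move.
The topography factor is dummy-coded with "cliff" as baseline; "Cameras"
is the two-camera indicator.

## Ecological (least-cost) distance

Per-pixel conductance is `c(s) = exp(α·z(s))` on the standardized
covariate (altitude by default), so the sign of α reads directly: positive
means high-covariate pixels are easier to traverse. The functional form is
a package choice — only the sign/interpretation is pinned down externally.
Adjacent mask pixels (8-neighbour; 4-neighbour available) are joined by
edges whose weight is the Euclidean step length times the arithmetic mean
of the two pixel *resistances* 1/c — a common SECR convention; averaging
conductances instead is a known alternative and deliberately not the
default. At α = 0 every edge weight equals its step length, so least-cost
distance reduces to the grid metric, which exceeds Euclidean distance by
at most the octile factor ≈ 1.0824 on a full rectangle. α is estimated
jointly with the SCR parameters; distance matrices are cached per α value
because finite-difference gradients revisit unchanged α constantly.

Distance from an arbitrary point snaps to the nearest pixel centre; exact
ties resolve to the lowest pixel index. Disconnected pixel pairs get +inf
with a warning rather than an error, so exclusion rules that split the
mask degrade gracefully.

## Habitat mask and covariate surfaces

The mask keeps every pixel centre within the buffer of at least one
detector, on a lattice anchored so a centre coincides with the detector
bounding-box minimum; an exclusion expression (e.g. `Altitude > 5200`)
drops unusable habitat. A 4σ buffer (the `suggest_buffer` default) leaves
detection probability at the edge at ~e⁻⁸ of its maximum. The terrain
ruggedness index is the per-cell root of summed squared elevation
differences to the 8 neighbours, with partial neighbourhoods at borders
(no padding). Moving-window smoothing uses a circular window of the
printed radius by default (1.5 km for ruggedness/livestock, 5 km for wild
prey); whether the original surfaces used circular or square windows is
not documented, so a square option exists. Livestock biomass combines
small- and large-bodied head densities with default unit masses of 35 and
250 kg (typical sheep/goat vs yak/cattle/horse body masses; the source
values are not published, and both are overridable). Rasters are ESRI
ASCII grids, planar meters, lower-left origin; no geodesy.

## Fitting and uncertainty

Quasi-Newton (L-BFGS-B, forward-difference gradients with step 1e-5,
objective tolerance 1e-8) from a fixed data-driven start: slopes 0,
density intercept from n/area, λ₀ from mean counts per individual-day, σ
from half the RMS between-detector displacement of recaptured individuals.
Because tiny SCR datasets are prone to a second, shallower mode in σ, two
restarts at halved and doubled starting σ are tried and the best kept; if
the line search ends abnormally a Nelder–Mead polish confirms (or
replaces) the point. The variance-covariance matrix is the inverse
central-difference Hessian at the optimum (relative step 1e-4); fits that
fail these checks are flagged, never raised. AIC = 2·npar − 2·logLik is
stored on every fit.

Derived abundance is `N̂ = Σ_s D̂(s)·a` with a delta-method SE on the link
scale and a lognormal 95% CI, `(N̂/C, N̂·C)` with
`C = exp(1.96·√ln(1+CV²))` — positive bounds, right-skewed, matching how
such intervals are conventionally reported. Model averaging renormalizes
Akaike weights over the chosen subset (top-k or ΔAIC ≤ cutoff) and
averages the density surfaces, not the coefficients; both full-set and
subset weights are exposed because cumulative covariate importance uses
the full-set weights.

## Independent encounters

Photograph bursts are reduced per (individual, detector): an event is kept
iff it is the first or at least 4 h (configurable) after the last *kept*
event. This greedy rule is idempotent and is the default; the alternative
("consecutive", comparing to the immediately preceding raw event) is
selectable since field protocols rarely state which is meant. Events with
a null individual id (unidentifiable photographs) are dropped with a
logged count when the capture history is built.

## Double-observer estimator

Chapman's bias-corrected two-sample estimator on groups, with Chapman's
variance. The published survey this reproduces prints SE(Ĝ) values of
3.45 / 0.57 / 1.51 for the three columns while the Chapman formula gives
1.37 / 0.58 / 1.51 — the first column disagrees and the variance actually
used there is not documented, so the Chapman SE is reported as such rather
than reverse-engineered. `SE(N̂)` combines SE(Ĝ) with the sample SE of
group sizes by the delta method; the CI for N̂ is normal-based
(symmetric), again matching reporting convention. Display rounding:
probabilities truncated to 2 decimals, Ĝ/Û rounded to 2, N̂ to integer.

## Synthetic studies: what they do and do not show

Covariate fields are kernel-smoothed Gaussian white noise, affinely scaled
to a configured centre/SD and clipped into realistic ranges (altitude
3,298–5,500 m, wild prey 0.01–0.58 /km², livestock up to ~11–14 head/km²);
a correlation length at or beyond the grid extent yields the constant-field
limit. The default structural truth uses the study-like values: density
slope 0.61 on standardized wild prey, two-camera effect 0.56 (plus
topography effects 0.44/0.74 in the full configuration), `log σ = 8.75`,
conductance α = 0.36, 80-day session, D̄ = 0.5/100 km².

`SimConfig.scaled_down()` is the replication workhorse: 25 detectors at
6 km spacing, σ = e^7.82 ≈ 2.5 km so the 4σ buffer (10 km) fits a
~1,300-pixel mask at 1.2 km spacing, and θ₀ = log 0.015 giving ≈ 20
detected individuals — small enough to fit in about a second, while keeping
the structural truth. Fifty replicates give median relative bias under 9%
for every structural parameter and 88–92% Wald coverage for the
intercepts.

One global seed spawns per-component child streams (landscape, detectors,
population, detections, double-observer survey), so each stage is
independently reproducible and ground truth is returned alongside the
records rather than reverse-engineered by tests.

What passing these tests does *not* show about real data: fields here are
stationary Gaussian surfaces (real covariates have ridgelines, valleys and
pasture polygons); individuals are identified without error (no partial or
single-flank identities); detector placement is a grid or a simple
prey-weighted draw, not sign-survey site selection; activity centres are
static points, not movement trajectories; and closure is exact by
construction.

## Known limitations

- Maximum likelihood only; no Bayesian/MCMC fitting, no open-population,
  multi-session or mark-resight models.
- The conductance model takes a single covariate.
- AICc is available as a manual computation from the stored npar/logLik
  but is not a table option; sample sizes here (n of individuals) make the
  small-sample correction ambiguous for SCR anyway.
- Block-level prey densities are plain pooled-count/area ratios; no
  detection correction at block level.
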