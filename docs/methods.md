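# Methods

`sympatry` studies how group size shapes within- and between-group
competition for space in a population of neighbouring primate groups. It
has three layers: a synthetic study system with known ground truth, the
spatial competition metrics computed from utilization distributions, and
the Bayesian models that estimate the effects. This note records the
models, the assumptions, the numerical choices, and what the synthetic
system does and does not emulate.

## The synthetic study system

The generator emulates a long-term field study: 10–13 habituated groups of
5–40 individuals (population mean ≈ 19) censused annually over ~30 years,
on a tropical dry-forest landscape crossed by a river, with a dry season
(January–April) and a wet season (May–December).

**Demography.** Each group's census size performs an integer random walk
(default step sd 1.5 individuals/year) reflected into [5, 40]. Both
seasons of a year share the annual census. Permanent fissions are
supported (a daughter group splits off with ~40% of members) but off by
default. Group size enters all models z-scored over the generated records.

**Climate.** A water-balance anomaly (SPEI-like) series follows an AR(1)
process over consecutive season steps (autocorrelation 0.6, emulating the
multi-month persistence of ENSO-driven spells) and is z-scored within
season, so negative values mean drier than typical *for that season*. The
6-month accumulation of a real SPEI product is not recomputed; the package
consumes a ready anomaly series and standardizes it.

**Landscape.** A 200×200 grid of 30-m cells (Landsat-like) with a
sinusoidal river. Dry-season greenness decays exponentially with distance
from the river (NDVI ≈ 0.65 at the river to 0.30 far from it, e-folding
900 m); the wet season is uniformly green and spatially flat. Each
seasonal window (Feb–Apr, Sep–Nov) yields three noisy RED/NIR scenes with
a QA contamination mask; composites are pixel-wise maxima of per-scene
NDVI. Reflectances are synthesized to produce the target NDVI exactly; no
sensor spectra, atmospheric effects or cloud-bit semantics are emulated.

**Space use.** Each group-season gets an isotropic Gaussian(-mixture)
utilization distribution (UD). The log of the true 95% area follows
`log A = a + 0.15·wet + 0.30·size_z + N(0, 0.15)`, so the size→area
effect is exact by construction. Dry-season centres are placed at the
distance from the river whose disc-averaged greenness equals a logit-scale
target `logit(NDVI) = −0.2 + (0.04 + 0.025·spei_z)·size_z` (inverted by
bisection on the noiseless dry field), encoding the dry-season
size→range-quality effect spatially; 120 m of placement noise is added.
Wet-season centres sit at a persistent per-group offset from the river
(sd 1200 m between groups, 150 m year-to-year wobble).

**Expansion dynamics.** A growing group's wet-season centre sweeps
tangentially around its nearest neighbour's range (0.04 rad per individual
of growth) with a slow radial closure (1.2% per individual). The sweep —
rather than a head-on approach — is what the range-shift measure can
detect: for convex ranges the overlap centroid lies between the two range
centroids, so a purely radial approach changes both groups' distances to
it by *exactly* the same amount (ΔD_A = −ΔD_B identically) and carries no
information about who moved. A perimeter sweep keeps the overlap zone
roughly equidistant from the static group while swinging it widely
relative to the expander, which is the signature the driver classification
picks up. This is a deliberate model of flanking encroachment, not a claim
about the only way real ranges shift.

**Movement.** Within a season, trajectories are exact discrete-time
samples of a stationary Ornstein–Uhlenbeck process around the UD centre
(relaxation 1 h, stationary spread equal to the UD spread), sampled at
5-min intervals for 12 h per tracked day; sleep sites are drawn from the
UD core. Mean travel speed is log-linear in size with slope
`beta_size_revisit + beta_size_hra`, so the composed revisitation rate
(speed × UD self-overlap, and self-overlap ∝ 1/area) carries the stated
total size slope `beta_size_revisit = −0.15`.

**Foraging.** Bite counts per focal follow are negative binomial
(gamma–Poisson, dispersion 1.5) with a log link, an offset for seconds in
view, group and individual intercepts, and a size slope of −0.2 modulated
by season × SPEI (steeper in anomalously dry dry-seasons and anomalously
wet wet-seasons, near zero when anomalies counterbalance the season).

**Dyadic outcomes.** Directed proportional overlap is drawn from the
hurdle-beta social relations model itself: correlated per-group focal and
neighbour effects (sd 0.4 each, correlation 0.3), correlated within-dyad
directed effects (sd 0.5, correlation 0.8), and fixed effects (neighbour
slope +0.25, focal × neighbour interaction −0.30, so the neighbour-size
effect is ≈ +0.6 for a focal group of ~8 and ≈ −0.2 at ~35). Symmetric
log encounter rates come from the multiple-membership model, with an
overlap-area slope of 0.40 that strengthens by +0.49 in the dry season
and an overlap-greenness slope of 0.42, plus a known per-row observation
SE of ~0.1 on the log scale. In the end-to-end pipeline the model-based
responses use the *geometric* overlap areas and zonal greenness as
covariates, while the purely geometric overlap panel feeds the
range-shift analysis.

**What passing tests do not show.** The generator matches the statistical
structure the inference stages assume — by design. Recovery here
demonstrates that the estimators are correct and calibrated under their
own assumptions, not that those assumptions hold for real trajectories,
real NDVI, or real social dynamics (irregular multi-modal ranges,
non-stationary movement, fission–fusion behaviour, observation gaps).

## Spatial metrics

**UD estimation.** Plug-in-bandwidth Gaussian KDE (per-axis Silverman
rule, h = sd·n^(−1/6)), computed by binning points to the 30-m grid and
convolving with a Gaussian kernel, renormalized to unit mass. This
replaces autocorrelation-informed kernel estimation; the simplification is
acceptable here because the synthetic UDs are stationary Gaussians and the
estimator is validated against their closed forms (mean within 2%, 95%
contour area within 5%).

**Home ranges.** Highest-density regions: cells accumulate in decreasing
density order until the level's mass is reached (ties at the threshold
break by count, so a uniform UD yields the level fraction of its support).
The boundary polygon comes from marching squares at the threshold; the
*reported* area is the included cell count × cell area, which a
brute-force sorted-cell accumulation reproduces exactly. The range
centroid is the UD-mass-weighted centroid of the included cells. Area SEs
come from a bootstrap over points (refit, re-threshold). 95% is the
default level for GPS-era ranges, 98% for sleep-site ranges; both are
configuration.

**Proportional overlap** PO_fn = IA_fn / HRA_f uses shapely polygon
intersection on the contour polygons; IA is symmetric, PO is not, and PO
is computed with polygon areas in both numerator and denominator so
PO ∈ [0, 1] holds to 1e-9 (the cell-mass area is reported separately).
**Encounter rates** are computed on full UD surfaces — the space–time
overlap semantics — as `area_scale × Σ p_i p_j × cell area`, exactly
symmetric, with an optional joint point-bootstrap SE. **Daily path
length** is total summed step length (equivalently mean speed × duration)
at the native sampling interval, with a block bootstrap (30-min blocks)
for the SE; days under 11 h are flagged rather than used. Note the naive
speed estimator is chord-length based: it is robust to subsampling only
for smooth paths, and shrinks for rough (diffusive) ones.
**Revisitation** is radius × speed × ∫p², linear in the radius by
construction; absolute values are comparable within this package only.

**Range shifts.** All forward period pairs of a dyad qualify as shift
events when directed overlap moves from < 25% to > 45% (strict, as
printed) and the net change in the size difference is ≥ 5 individuals;
if both directions jump, the direction with the larger increase reports
the event. ΔD = D_{t+i} − D_t with D the distance from a group's range
centroid *at time t* to the overlap centroid at each time; the group with
the larger |ΔD| drove the shift; exact ties are labelled indeterminate
and excluded from the driver proportion (measure zero for continuous
geometry). The pipeline runs this analysis on wet-season ranges per year
— one centre per group-year — because a dry+wet mixture would place two
centres per group and blur the centroid geometry.

## Bayesian inference

No general-purpose MCMC framework is used; the package implements its
posterior machinery directly, with hand-derived analytic gradients for
every likelihood.

**Engine.** Each model is a differentiable negative log posterior over a
packed parameter vector with scales on the log scale and correlations on
the atanh scale. The joint mode is found by bounded L-BFGS (restarting
from the incumbent until the gradient is small); the Hessian at the mode
is built by central finite differences of the analytic gradient; draws are
sampled from the resulting Gaussian. Random effects use the non-centered
parameterization (`effect = sd × z`, z standard normal), which removes
the unbounded density spike at sd → 0 that breaks joint-mode inference in
the centered form.

**Priors** are weakly regularizing: Normal(0, 1) on standardized-scale
slopes, Normal(0, 10) on intercepts (whose natural scale is a log rate or
log area, far from zero), half-Normal(0, 1) on standard deviations,
Normal(0, 1) on log-scale auxiliaries (dispersion, shape, precision), and
an LKJ(2)-type prior on 2×2 correlations.

**Families.** Negative binomial is mean–dispersion with a log link and
exposure offset; gamma is mean–shape with a log link; beta is
mean–precision with a logit link (responses at exactly 0 or 1 are nudged
by 1e-6 and the count logged); Gaussian responses fold a known per-row SE
into the residual variance. Measurement error on a gamma response is
marginalized analytically via the exact log-gamma moments — log y is
treated as Gaussian with mean ψ(k) − log k + log μ and variance ψ₁(k)
plus the known SE² — because joint latent-mode inference for that model
is degenerate (the shape diverges along a density spike).

**Hurdle-beta SRM.** Two linear predictors (logit hurdle probability of
zero overlap; logit beta mean of positive overlap) share one set of
varying effects by default — per-group focal/neighbour pairs correlated
within group, directed dyad pairs correlated within dyad — with
branch-specific fixed effects; a toggle gives each branch its own
effects. The exact branch-sharing of the published model is not public,
so the shared structure is this package's canonical choice. Because the
joint mode locates variance and correlation hyperparameters poorly in
either parameterization (centered: spike at ρ=1; non-centered: biased
low), the six hyperparameters are inferred from their *marginal*
posterior by nested Laplace: an inner Newton solver with an analytic
Hessian profiles the latent field at each hyper value, a log-determinant
correction completes the Laplace integral, Nelder-Mead (with a
deliberately spread initial simplex — correlations start at 0 and the
default simplex would probe them at a 2.5e-4 scale) finds the hyper mode,
and a finite-difference Hessian plus linear propagation of hyper
uncertainty into the latent draws yields the joint draws. Verified
against truth: ρ_dd = 0.8 recovers with posterior medians 0.74–0.86
across scales.

**Multiple-membership model.** Gaussian on log encounter rate with known
per-row SE; each row loads on both member groups' effects with equal
weight plus a dyad intercept. The symmetric pair sum is grouped before any
other addition so the posterior is *bitwise* invariant to swapping the two
group labels in any row. Hyperparameters stay at the joint-Laplace stage;
fixed effects are what the downstream summaries use, and their coverage is
verified by simulation.

**Summaries.** Posterior medians, 89% highest-density intervals (shortest
contiguous interval over sorted draws) and PP>0 (share of draws above
zero). Conditional neighbour-size slopes are evaluated per draw at focal
sizes of 8, 21 and 35 individuals using the size z-scaling stored with the
fit; seasonal contrasts are per-draw wet − dry differences; marginal size
slopes are evaluated at representative SPEI values −1.5, 0 and +1.5.
Split-R̂ and draw counts are reported per summary; draws are iid from the
Gaussian approximation, so R̂ ≈ 1 by construction and is a sanity check
rather than a mixing diagnostic.

**Calibration.** Fixed-truth recovery over 20 seeded replicates per
family checks that 89% HPDIs cover the generative value for every fixed
effect (binomial tolerance [0.7, 1.0] at 20 replicates): the negative
binomial intake model with the three-way SPEI interaction (12 groups × 8
years, ~1500 follows), the seasonal hurdle-beta SRM (12 groups × 8
season-periods), and the seasonal multiple-membership model (15 groups ×
6 season-periods). These sizes were chosen to mirror the study's data
volumes at a scale the full suite can re-run routinely.

## Numerical choices and defaults

- Grid convention: cell centres, metres, origin at the lower left; zonal
  means use the cell-centre-in-polygon rule with no partial-cell weights.
- Missing values propagate through NDVI arithmetic; composites skip them;
  an all-missing cell stays missing.
- SPEI standardization uses the n−1 denominator.
- Seasonal composite windows: February–April (peak dry),
  September–November (peak wet).
- One master seed fans out to per-layer substreams by SHA-256 hashing of
  layer names, so adding a layer never perturbs existing draws; identical
  (config, seed) runs are reproducible end to end.
- Default pipeline scenario: 12 groups, 24 years (2000–2023), 12 focal
  individuals per group with 2 follows per season, one tracked day per
  group-season, 2000 posterior draws per model. The full run takes about
  half a minute and the problem sizes are stated in the run's summary.
- Rasters are exchanged as ESRI ASCII grids and polygons as GeoJSON-style
  JSON; both are plain text.

## Known limitations

- Posterior uncertainty is a Gaussian approximation; heavy-tailed or
  multimodal posteriors would be misrepresented. The calibration study
  bounds the practical consequence for the fixed effects reported.
- GLMM variance components use joint-mode inference and can be biased;
  only the SRM's hyperparameters receive the nested-Laplace treatment.
- The ΔD driver measure is uninformative for purely radial range shifts
  of convex ranges (exact tie); the reported driver proportions are about
  flanking dynamics, which the generator makes explicit.
- Absolute revisitation and encounter values are relative quantities,
  comparable within this package's conventions only.
- The daily path length estimator underestimates distance on rough
  trajectories relative to velocity-model-based estimators.
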