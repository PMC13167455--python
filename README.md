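# sympatry

Spatial competition between neighbouring animal groups: a tested,
fully-synthetic re-implementation of the analytical machinery used to ask
how group size shapes within- and between-group competition for space in
long-term primate field studies.

Real analyses of this kind rest on restricted GPS data. `sympatry`
instead builds a synthetic study system with known ground truth — three
decades of group censuses, a seasonal climate-anomaly series, a riparian
landscape with satellite-like greenness scenes, per group-season
utilization distributions, focal foraging records, and model-generated
dyadic outcomes — and then runs the full analysis pipeline on it, so
every stage can be validated by analytic oracles and parameter recovery.

**Who it is for:** movement and behavioural ecologists who want a
verifiable reference implementation of these dyadic spatial analyses, and
methodologists who want a calibrated testbed for hierarchical dyadic
models.

## The models

*Spatial metrics.* For groups *f*, *n* with home-range polygons at a UD
level, directed proportional overlap is

    PO_fn = IA_fn / HRA_f

(IA the intersection area — symmetric — and HRA_f the focal range area,
so PO is asymmetric). The symmetric encounter rate of groups *i*, *j*
with UDs p_i, p_j is the space–time overlap integral

    ER_ij = a · ∫ p_i(x) p_j(x) dx

at a reference area a (1 m² by default), and the revisitation rate is
radius · speed · ∫ p². Range-shift events are dyad-period pairs where
PO jumps from < 25% to > 45% while the size difference changes by ≥ 5
individuals; the group whose distance to the overlap centroid changed
more (|ΔD|, ΔD = D_{t+i} − D_t) is classified as the driver.

*Group-level GLMMs.* Fruit intake is negative binomial with a log link
and an observation-time offset; areas, path lengths and revisitation
rates are gamma; range greenness (mean NDVI) is beta on a logit link.
All models take z-scored group size, season, their interaction, and
optionally the three-way size × season × SPEI interaction, with varying
intercepts by group (plus individual or year), and measurement-error
terms where the response carries a known SE.

*Dyadic models.* Directed overlap follows a zero-augmented (hurdle) beta
social relations model: a Bernoulli hurdle for zero overlap and a beta
density for its degree, with correlated per-group focal/neighbour effects
(g_i, r_i), correlated within-dyad directed effects (d_ij, d_ji), and
focal size × neighbour size fixed effects. Log encounter rates follow a
symmetric multiple-membership model: each observation loads on both
member groups' random effects with equal weight, plus a dyad intercept,
with symmetric predictors (|size difference|, overlap-zone area, overlap
greenness), each optionally interacted with season.

Posteriors are approximated by MAP + Laplace with analytic gradients;
the SRM's variance/correlation hyperparameters are inferred from their
latent-integrated marginal posterior by nested Laplace. Summaries are
posterior medians, 89% HPDIs and PP > 0. See `docs/methods.md` for the
full account.

## Worked example

`examples/03_dyadic_models.py` generates dyadic data from the known truth
and fits both dyadic models:

```
SRM on 3168 directed dyad rows (987 zeros)
  b_focal      -0.25 [-0.33, -0.16]  truth -0.30
  b_neighbour  +0.29 [+0.20, +0.38]  truth +0.25
  b_fn         -0.32 [-0.37, -0.27]  truth -0.30
  rho_dd       +0.73 [+0.61, +0.85]  truth +0.80
neighbour-size slope by focal group size (the encroachment gradient):
  neighbour_slope[focal=8]     +0.72 [+0.62, +0.84]  PP>0 1.000
  neighbour_slope[focal=21]    +0.21 [+0.12, +0.29]  PP>0 1.000
  neighbour_slope[focal=35]    -0.35 [-0.49, -0.21]  PP>0 0.000

MM on 1584 pair-period encounter rates
  b_area       +0.40 [+0.39, +0.42]  truth +0.40
  b_ndvi       +0.42 [+0.40, +0.44]  truth +0.42
  b_size_diff  -0.02 [-0.05, +0.02]  truth +0.00
  wet-dry overlap-area contrast -0.50 [-0.53, -0.48]  truth -0.49
```

Read: a larger neighbour encroaches strongly on a small focal group
(slope +0.72 at ~8 monkeys) but not on a large one (−0.35 at ~35); the
within-dyad correlation of the two directed relationship effects is
recovered near its generative value; and shared space converts to
encounters faster in the dry season (negative wet − dry contrast). The
other examples build the study system, compute the spatial metrics, and
run the whole pipeline (`examples/04_full_pipeline.py`, ~30 s). A thin
CLI wraps the pipeline: `sympatry all --out run --seed 1`.

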