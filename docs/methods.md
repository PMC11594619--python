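# Methods

This note documents the models, defaults, and design choices behind
`hostsdm`, and what the synthetic experiments do and do not demonstrate.

## Data model

Every gridded quantity is a `Raster`: values plus a nodata mask on a
regular WGS84 lon/lat `GridSpec` (square cells, row 0 northernmost,
upper-left origin). Cell membership follows the floor convention on
`(coord − origin) / cell_size` with a 1e−9-cell snap tolerance, so a point
constructed exactly on a shared edge deterministically lands in the
upper-index cell; converting cells back to points uses cell centers. The
working resolution throughout is 2.5 arc-min (≈ 4.6 km at the equator).
All distances are great-circle on a sphere of radius 6371.0 km; no
projected CRS is supported. Occurrence thinning keeps the first record per
cell per species in input order, which makes it deterministic and
idempotent.

## Synthetic landscapes and virtual species

The generator emulates the data regime of a presence-only study of a
montane, host-specialized herbivore:

- **Climate layers** (default 19, named bio1…bio19 by the usual
  temperature/precipitation convention, plus elevation) are smoothed
  Gaussian fields (default correlation length 6 cells on a 120×100 grid).
  The realized covariance of the smoothed fields is whitened before a
  Cholesky mix, so the stochastic parts carry the target cross-layer
  correlation exactly rather than only in expectation. Temperature layers
  add a latitudinal gradient and a −6.5 K/km elevational lapse;
  precipitation layers are exponentiated to stay positive, which makes
  multiplicative "future" shifts well defined. The default correlation
  matrix contains several pairs above 0.85 so the collinearity filter has
  real work to do. Layer typing (temperature vs precipitation) is declared,
  never inferred.
- **Species truth** is an inverse-logit of additive response terms
  (Gaussian or logistic in a named layer) plus, for the focal species, a
  host term `w · richness / max(richness)`. The six default hosts have
  staggered Gaussian optima along bio1 (spacing 1.6 SD of the optimum
  ladder) and a shared moisture preference, giving each ~10–17% landscape
  prevalence and a fragmented richness surface. The default focal species
  combines a thermal optimum, a mid-elevation optimum (SD 350 m), and a
  dominant host term (w = 6 against climate weights of 1.5); its baseline
  intercept is −7 with the host term active and −2.4 without, keeping
  landscape prevalence near 15–20% in both regimes.
- **Presence-only sampling** draws cells without replacement with
  probability proportional to truth × an optional effort (bias) layer, and
  places records at cell centers — records arrive pre-snapped to the grid,
  as after thinning. **Future climates** are monotone shifts: additive for
  temperature, multiplicative for precipitation.
- **The expert range** polygonizes cells with truth ≥ 0.3, dilates by
  12 km, and can jitter vertices. These defaults were chosen so the
  polygon behaves like a real expert map — generous edges that contain
  ≥ 95% of presences sampled from truth (measured 95–99% across seeds)
  while still excluding a meaningful fraction of the landscape.

What the generator does **not** emulate: dispersal limitation, observation
error in coordinates, temporal turnover, spatially varying survey effort
beyond the single bias layer, and realistic GCM spatial structure in
future anomalies. Passing tests therefore demonstrate statistical
correctness of the machinery under a known truth, not robustness to those
real-data pathologies.

## Maximum-entropy core

The model is the penalized presence/background formulation: minimize

    −mean_pres[β'f] + log Σ_bg exp(β'f) + Σ_j λ_j |β_j|

Feature classes default to {linear, quadratic, hinge} with 20 hinge knots
per direction per variable, all normalized to [0, 1] by the training
background min/max. Penalties are λ_j = λ_mult · c_class · sd_j /
√n_presence with class constants 1.0 (linear, quadratic, product,
threshold) and 0.5 (hinge); the penalty is thus on the order of the
sampling noise of the corresponding constraint, so with no signal
coefficients stay at exactly zero. The optimizer is FISTA with
backtracking line search, momentum restart, and soft-threshold prox;
convergence is declared when the relative objective change falls below
1e−5 (cap 10,000 iterations; non-convergence is flagged and warned).
Degenerate (constant) features are dropped with a warning.

Outputs: raw `q(x) = exp(β'f)/Z` (Z summed over the training background,
so the Gibbs density integrates to 1 there — asserted to 1e−9 in tests);
cloglog `1 − exp(−e^H q)` (default; H = background Gibbs entropy, so the
null model maps to the constant 1 − e⁻¹); logistic `e^H q / (1 + e^H q)`.
The exponent is clipped at ±700/50 before exponentiation; both sigmoids
saturate far below the clip. Projection reuses the training Z and H, so
predicting on the training layers reproduces training-time values exactly.

A small grid search (`tune_maxent`) over λ_mult ∈ {0.5, 1, 2, 4} × feature
sets, selected by mean held-out AUC, stands in for external tuning
packages. The comparative model is a random forest
(scikit-learn, 500 trees, min leaf 2, presence = 1 vs background = 0,
class-1 probability as suitability).

Background samples are drawn with replacement proportional to an optional
weight raster; supplying the selected offset layer as the weight is the
bias-file mechanism. Presence cells are excluded from the background
candidate set — a deliberate deviation from tools that allow overlap,
giving a cleaner likelihood.

## Expert-range offset priors

The offset family has three parameters. Inside the range polygon the
unnormalized weight is 1. Outside, with d the signed great-circle distance
to the boundary and x = d/d95 clamped to [0, 1] (d95 = 95th percentile of
outside distances), the weight is `1 / (1 + exp(s · (x − skew)))`. The
rate dial maps to steepness via `rate_norm = clip((log10 rate + 3)/4, 0, ∞)`
and `s = 4 ln(10) · rate_norm`, i.e. the conventional grid
{0, 0.01, 0.1, 10} maps to steepness {0, 2.30, 4.61, 9.21}; at rate 10 the
curve falls through roughly two decades across the normalized transect,
and rate 0 is flat outside. Inside and outside masses are rescaled so the
inside holds exactly `prob` of the total and the layer sums to 1.

Selection treats each normalized layer as a discrete distribution over
cells: lnL = Σ log(value at presence cell), AIC = 2k − 2 lnL with k = 3.
A presence on a zero-mass cell disqualifies the candidate. The closed form
for a uniform prior (AIC = 6 + 2n ln N) anchors the unit tests.

## Verification metrics and comparison

- AUC: Mann–Whitney with ties counted ½.
- TSS: sensitivity + specificity − 1; when no threshold is given it is
  maximized over all unique observed scores, and that same threshold
  builds the confusion table for ORSS and SEDI (standard practice;
  deterministic).
- ORSS: (ad − bc)/(ad + bc); NaN (flagged) when ad + bc = 0.
- SEDI: log-rate form with hit and false-alarm rates clamped into
  [1e−6, 1 − 1e−6].
- Continuous Boyce: 101 overlapping windows of width 0.1 × score range;
  Spearman correlation of predicted-to-expected ratios against window
  midpoints; windows with zero expected mass are skipped; constant maps
  give flagged NaN.
- Wilcoxon signed-rank: zero differences dropped; exact null for n ≤ 25
  without ties, otherwise the normal approximation with tie correction
  (scipy backend).

`compare_combinations` reuses one set of seeded 75/25 presence splits
(test size = ⌈0.25 n⌉, so 57 presences split 42/15) across all predictor
combinations and model kinds, pairing replicates by index, and reports a
paired two-tailed Wilcoxon p per metric and combination pair. Variable
importance is permutation-based (held-out AUC drop, 10 seeded permutations
per layer, negatives floored at zero, normalized to 100%), with
alone/leave-one-out jackknife AUC panels on the first replicate's split.

### A calibration caveat that matters

With a single fixed presence sample, the replicate-paired comparison tests
the *conditional* hypothesis "the extra layer does not help for this exact
presence draw". That hypothesis is almost surely false even when the layer
is scientifically irrelevant: any covariate has a chance association with
a finite draw, the shared splits give the paired test essentially
unbounded power against it, and in the default scenario host richness is
in addition a deterministic nonlinear transform of the focal species' own
climate driver. The package's null-calibration experiment
(`evaluation.null_host_calibration`) therefore (a) builds worlds where the
hosts respond to moisture while the focal species responds only to
temperature and elevation, and (b) draws a fresh presence sample per
replicate — the design under which replicate differences are independent
and symmetric when no host effect exists, making uniform p-values the
correct target. It also runs at λ_mult = 0.3: at the default penalty the
L1 fit frequently zeroes the richness coefficients, the two models
coincide exactly, and the all-zero-difference Wilcoxon degenerates to
p = 1 (a conservative artifact that makes uniformity unmeasurable rather
than false). The flip side of this analysis is a caveat on replicate-based
significance claims computed on real data, where presence resampling is
impossible: such p-values overstate evidence at the dataset level.

## Path analysis

Standardized piecewise linear models: `richness ~ energy + water +
elevation` and `focal ~ energy + water + elevation + richness`, fit by OLS
on z-scored variables; the indirect effect of an abiotic variable is its
richness path times the richness→focal path, total = direct + indirect.
"Energy" and "water" are the first principal components of the
temperature-type and precipitation-type layers (orientation fixed to
correlate positively with the group mean; grouping configurable). Designs
with condition number above 1e8 are rejected. No latent variables, no
d-separation machinery.

## Niche overlap

PCA (2 axes) of the standardized climate values of all landscape cells,
with a deterministic sign convention (largest-magnitude loading positive).
Occurrence densities are histogram-plus-Gaussian-smoother estimates on an
R×R grid over the background score extent (default R = 100 for desk-scale
speed; 1000 supported), bandwidth per axis by Silverman's rule, multiplied
by the available-environment indicator and renormalized to sum 1.
D = 1 − ½Σ|z₁−z₂|; I = 1 − ½Σ(√z₁−√z₂)². The similarity null relocates
one density by random wrapped grid shifts within the background support
(the zero shift is excluded); p = (1 + #{null ≥ observed})/(reps + 1).
Niche dynamics use occupancy masks at density quantile 0 (all cells with
any density; configurable): expansion and stability weight the host
density renormalized over its mask (so they sum to 1 exactly), unfilling
weights the focal density over its own mask.

## Threat assessment

EOO is the spherical area (fan triangulation, l'Huilier excess) of the
planar convex hull of the occupied points; fewer than three non-collinear
points fall back to the AOO, and EOO is floored at AOO. AOO counts
occupied cells of a fixed 2×2 km planar grid anchored at the (0,0)
graticule after per-point equirectangular scaling (origin optimization,
which IUCN permits, is noted but not implemented). Criterion-B bands:
CR below EOO 100 / AOO 10, EN below 5,000 / 500, VU below 20,000 / 2,000
km²; the worse of B1/B2 wins and the criterion string records which fired.
IUCN does not define NT numerically; following common automated-assessment
practice the package flags NT within a configurable margin (default 1.5×)
of a VU threshold on either metric. Only range geometry is assessed;
subcriteria (fragmentation, continuing decline) are annotations. Because
EOO is floored at AOO, probing the B1 boundary in isolation requires
holding AOO at a non-threatening value *below* the probed EOO range
(e.g. 3,001 km²), not at a large value.

Threshold sweeps assert AOO monotonicity; scenario trends additionally
report remaining/shrinking/gained cell counts against the current map and
flag total range loss as extinction (category CR).

## Problem sizes used in the tests

Unit and property tests run on reduced worlds (60×50 or smaller grids,
~120 presences, 300–1,000 background points, linear+quadratic features)
chosen so the full suite completes in about a minute while keeping every
statistical check adequately powered. The end-to-end recovery checks use
the full default scenario (120×100 grid, 200 presences, 2,000 background,
100 paired replicates); the null calibration uses 200 reduced runs of 12
replicates each. The pipeline default is 20 replicates and 2,000
background points; raising them to 100/10,000 is a config change.

## Known limitations

- The maxent implementation targets the standard penalized formulation,
  not numerical equivalence with any particular historical implementation;
  feature constants and default penalties are this package's documented
  choices.
- The offset family is a fixed logistic-in-normalized-distance form; the
  three parameters play their conventional roles but other decay families
  exist, and AIC comparisons are meaningful only within the family.
- Signed distance to a polygon uses a local equirectangular approximation
  per segment — accurate at regional scales, not for polygons spanning
  tens of degrees or polar regions.
- The AOO grid origin is fixed; true IUCN practice allows origin
  optimization, which can change AOO by up to a factor ~2 for sparse
  point sets near the threshold.
- Replicate-based model-comparison p-values are conditional on the
  presence sample (see the calibration caveat above).
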