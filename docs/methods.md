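# Methods

`invadescape` studies how landscape composition and spatial structure
interact with invader traits to shape plant invasions. It couples four
pieces: a synthetic landscape generator, a stochastic invasion simulator, a
FRAGSTATS-style landscape-metric battery, and a two-stage Bayesian
regression analysis. This note records the models, the defaults and why
they were chosen, the numerical conventions, and what the synthetic setting
can and cannot show.

## Synthetic landscapes

Rasters are square grids of 11 habitat-class codes (unsuitable = 0,
grassland = 1, deciduous forest, coniferous forest, mixed forest, pasture,
crop, road, wetland, water, shrubland = 10), default 216 x 216 cells of
30 m — the scale of a 6.48 km land-cover tile. Generation follows a
modified-random-clusters scheme: a sub-critical site-percolation mask
(occupation probability `0.45 * (1 - fragmentation)`, capped below the
4-neighbor percolation threshold so no giant clump defeats the composition
targets) is labeled into clumps; off-mask cells are singletons; clumps are
assigned classes in a seeded random order with probabilities proportional
to each class's unfilled target cell count. This keeps realized proportions
within 0.05 of the targets while spanning a fragmentation gradient from a
few large patches (`fragmentation -> 0`) to salt-and-pepper texture
(`fragmentation = 1`).

Roads are straight polylines joining two opposite raster edges, thickened
to the requested width; they are stamped last and overwrite other classes,
so each road is one 8-connected patch spanning a full raster dimension.
Water bodies are stamped disks. Tiles are required to be mostly terrestrial
(water < 50%); generation retries with a derived seed and fails loudly if
the target composition cannot satisfy that.

Rasters serialize as ESRI ASCII grids. NODATA cells are rejected on read:
pipeline rasters must be fully classified.

## Invasion simulator

Annual time steps, two stages (first-year juveniles, perennial adults), on
one raster. Habitat quality enters through three per-class quantities:

- expansion rate `r_i` (yr^-1): grassland 0.5, with other suitable classes
  at fixed fractions of it (pasture 0.7, deciduous 0.6, mixed/shrubland
  0.5, coniferous 0.4, wetland 0.3, crop 0.1; road/water/unsuitable 0);
- carrying capacity `K_i`: 100 adults/cell in grassland, scaled by the same
  fractions;
- establishment scaling `r_i / r_grassland` in [0, 1].

Fecundity is 200 seeds per adult per year. The dispersal kernel is
log-normal in distance (median 60 m = two cells, log-sd 1.0) with uniform
direction; a trait multiplier scales distances. These defaults were chosen
so that, across the trait grid, outcomes span failure through landscape
saturation within 100 years — the regime the analysis needs — and they all
live in `HabitatParams` / `DispersalKernel` for ad-hoc replacement.

The yearly update order: (1) juveniles mature; (2) local growth adds
`r_i * growth_mult * N * (1 - N/K_i)` expected adults in occupied cells,
realized by stochastic rounding (floor plus a Bernoulli trial on the
fraction — integral counts without systematic bias); (3) each adult sheds
seeds, and each seed's establishment trial factorizes as
`establishment_freq * (r_i/r_grassland)`, so dispersal is thinned
binomially by `establishment_freq` at the source and only candidates get
displacement draws (an exact reformulation that keeps the computation
tractable); (4) a candidate landing on a road rides the corridor with
probability `corridor_usage`: it moves a kernel-drawn distance along the
8-connected road network (graph distance, capped at the network's extent)
and is deposited at the nearest non-road cell to its exit, Euclidean ties
broken N, E, S, W, then clockwise diagonals; (5) candidates in unoccupied
suitable cells found juveniles with probability `r_i/r_grassland`
(road/water/unsuitable establish nothing); (6) adults are truncated at
`K_i` on regulated cells. Seeds leaving the raster are lost (tiles are
landscape samples; no wraparound), there is no seed bank, and corridor
transport is a single draw per seed, not a chain.

Adults are immortal on suitable habitat; founders placed on zero-growth
classes die after 5 years (`founders_on_unsuitable_die`), which isolates
the degenerate all-barrier scenarios without touching normal dynamics.

Founding: 50 adults in each cell of the central 3 x 3 block; on even-sided
rasters the block anchors at `((rows-3)//2, (cols-3)//2)`.

Four responses summarize a run: mean yearly increment of occupied-cell
proportion over the first 30 years (expansion rate); mean of yearly
population ratios over the same window (growth rate) — years with zero
population are skipped and counted, since the ratio is undefined; occupied
proportion at the final year (final extent); and mean adults per cell at
the final year (final population). "Averaged across the landscape" is read
as total adults over total cells (not per occupied cell), the arithmetic
(not geometric) mean is used for the growth ratios, and occupancy counts
cells with at least one adult. Runs shorter than 31 years compute the
transient metrics over the available window and record it.

The full factorial trait grid crosses dispersal multipliers
{0.33, 0.5, 1, 1.5, 2}, growth multipliers {0.33, 0.5, 1, 1.5, 2},
establishment frequencies {0.005, 0.01, 0.025, 0.05} and corridor usage
{0, 0.25, 0.5, 0.75, 1} — 500 combinations; on 1000 landscapes that is the
500,000-simulation full-scale design, which the planner enumerates but
desk-scale runs subsample.

## Landscape metrics

Fifty metrics per raster, fixed order: 11 class proportions, then NP, PD,
LPI, TE, ED; area, radius of gyration, shape index, fractal index,
perimeter-area ratio, circumscribing circle and contiguity distributions
(area-weighted mean / median / population SD each); PAFRAC; ENN
distribution; contagion, PLADJ, IJI; patch richness, Shannon and Simpson
diversity and evenness; aggregation index. Conventions follow FRAGSTATS
v4: 8-neighbor patch delineation, 4-neighbor adjacency tallies with the
double-count method, areas in hectares, ED in m/ha, percent metrics in
[0, 100]; the landscape boundary is not counted as edge (no border file),
while patch perimeters do include raster-edge segments. Core-area and
contrast families are out of scope (they need edge-depth and contrast
weights the analysis does not define).

Choices worth stating explicitly:

- Shape index uses the raster normalization (perimeter over the minimal
  perimeter of an equal-cell-count patch), so a square scores exactly 1.
- The circumscribing circle is the exact smallest enclosing circle of the
  patch's cell corners (Welzl's algorithm on the convex hull); the oracle
  recomputes it by enumerating hull pairs/triples.
- Contiguity uses the 3 x 3 template (center 1, rook 2, diagonal 1;
  template sum 13); a one-cell patch scores 0.
- PAFRAC is twice the OLS slope of ln(perimeter) on ln(area) over all
  patches; with fewer than 10 patches it is flagged low-confidence, and
  with a degenerate regression (one patch, or all equal areas) it is
  imputed 1 and flagged.
- ENN is the minimum cell-center distance to another patch of the same
  class; patches with no same-class partner are excluded from the
  distribution, and if no patch has one the three ENN summaries are imputed
  as the raster diagonal and flagged.
- Contagion is 100 by convention on a single-class raster. IJI needs at
  least three classes: one class imputes 0, exactly two classes impute 100
  (the single class pair is trivially evenly interspersed). Single-cell
  classes contribute zero to AI while keeping their area weight.

Imputation (rather than dropping) keeps every metric vector complete for
the downstream regression; every imputed entry raises a named flag that is
carried into the metrics CSV.

Every metric family has a brute-force twin in `metrics_oracle` —
independent flood-fill labeling, explicit adjacency loops, closed-form
summaries — and the test suite requires agreement within 1e-9 on random
rasters. The two paths share only the metric definitions and the degenerate
conventions above.

## Stage 1: Bayesian lasso

For one (trait combination, response) pair, the response across landscapes
is regressed on the 50 metrics, centered and scaled with training moments
(constant training columns are dropped with a warning and re-inserted as
zero coefficients downstream). Priors: independent Laplace(0, rate tau) on
the 50 coefficients, Normal(0, variance 100) on the intercept (a precision
of 0.01 — the precision parameterization matches the Gibbs-sampler dialect
these priors are conventionally written in), Uniform(0.001, 30) on the
residual scale sigma. The shrinkage rate tau is not given a hyperprior: it
is fixed per fit and selected over a log-spaced 24-point grid on
(0.1, 2000] by the summed out-of-sample log predictive density on a
held-out landscape split (10% by default; 900/100 at full scale, one shared
split across all trait combinations). A grid cannot include rate 0, so the
smallest grid point stands in for near-zero shrinkage. Ties prefer the
larger rate (more parsimony), and the selection records whether the optimum
was interior or at a grid boundary — boundary-minimum selections are the
asymptotic flat-score cases.

Sampling is Gibbs via the exponential scale mixture of the Laplace prior:
beta_j | eta_j ~ Normal(0, eta_j) with eta_j ~ Exponential(rate tau^2/2),
giving a jointly Gaussian coefficient block (Cholesky draw), inverse-
Gaussian updates for 1/eta_j, and a truncated inverse-gamma for sigma^2
(sampled by rejection from the untruncated conditional, pinned to the
nearer bound when the conditional mass sits entirely outside the truncation
interval). Three chains by default; convergence is monitored with the
classic Gelman-Rubin between/within variance ratio per parameter, and any
statistic above 1.1 triggers one retry with doubled iterations before the
fit is flagged non-converged. Chain geometry presets: `full` (10000 kept
after 5000 burn-in), `reduced` (2000 after 1000 — the default for tests and
desk-scale runs), `smoke` (800 after 400). The out-of-sample score is the
summed (not mean-per-point) log predictive density; selection is invariant
to that choice.

The sampler is cross-checked two independent ways in the tests: against an
affine-invariant ensemble sampler (emcee) run on the identical unnormalized
posterior of a 3-predictor toy problem, and against a coordinate-descent
lasso MAP at the matched penalty for sign agreement.

## Stage 2: trait interactions

For one metric and one response, the stage-1 posterior-mean coefficients
across all trait combinations become the response of a Gaussian linear
model on the four trait values: Normal priors with precision 0.001
(variance 1000) on the intercept and the four trait coefficients Phi, and
the same Uniform(0.001, 30) prior on sigma (the stage-2 model statement
leaves the residual prior implicit; reusing the stage-1 choice keeps the
two stages consistent). Trait columns are centered and scaled before
fitting so Phi magnitudes are comparable across multipliers and
frequencies; stage-1 inputs are the raw posterior means, not the
relative-importance rescaling. A trait "interacts" with a metric when the
95% equal-tailed credible interval of its Phi excludes 0. Relative
importance within one fit is |beta| scaled by the largest |beta|, with
signs reported separately.

## Pipeline, seeding, scale

The experiment composes the stages with plain-text outputs (ASCII rasters,
CSV, JSON) and a manifest. Per-job seeds come from a counter-based
splitmix64 hash of (master seed, job index), so any grid subset reruns
identically; the stage-1 holdout split uses one derived seed shared by all
combinations. Stage failures are recorded in the manifest and never abort
the grid.

Three presets. `full` reproduces the full design counts (1000 landscapes
of 216 x 216, 500 combinations, 100 years, 24 shrinkage rates, 900/100
split — 500,000 simulations, enumerable but not meant to run on a desk).
`smoke` (5 landscapes of 64 x 64, 8 trait combinations, 40 years, 8
shrinkage rates, 2000 MCMC iterations per chain) exercises every stage end
to end in minutes and anchors the schema and determinism checks; with only
4 training landscapes, its stage-1 posteriors are fully shrunk — by design
the holdout score cannot prefer anything beyond the intercept there.
`headline` is the smallest scale at which stage-1 inference is meaningful:
40 landscapes of 56 x 56 whose grassland share spans 5-80% (with an
independent crop gradient, a small fixed developed fraction, and a random
vegetated remainder, so no other class is a mirror image of grassland), 8
moderate trait combinations, and an 18-year horizon at which spread is
still radius-limited. That non-equilibrium horizon matters: once every
suitable cell is colonized, final extent collapses into an arithmetic
identity of the barrier fractions and carries no dynamical information.
The analysis scripts run the headline panel with all four responses; the
acceptance checks use it for the habitat-quality headline. Test and
acceptance problem sizes (32 to 64-cell rasters, 100 replicates, reduced
chain lengths) are chosen so the full battery completes on one CPU while
keeping every check statistically meaningful at its stated threshold.

## What the synthetic setting does and does not show

The generator reproduces the features the analysis manipulates —
controllable composition, a fragmentation gradient, linear corridors, water
barriers — but not the spatial regularities of real land cover: field
geometry, road networks with junction structure, riparian corridors
correlated with topography, or the empirical joint distribution of
composition and configuration found in national land-cover samples.
Passing tests therefore demonstrate that the machinery measures what it
claims to measure (metrics match their definitions; the simulator responds
to traits and habitat as specified; the regressions recover planted
signals at the stated rates), not that any particular real landscape
carries a particular invasion risk. Demography is likewise a minimal
two-stage skeleton, not a calibrated life table for any particular species;
conclusions transfer only at the level of qualitative structure
(habitat-abundance dominance, direction of trait interactions).

Known limitations: no equilibrium is reached by year 100 (final-state
metrics are horizon-dependent by design); the growth-rate response is
undefined in extinction years and is averaged over the defined ones;
corridor transport is single-hop; establishment ignores propagule pressure
beyond the first founder in a cell-year; and with very few landscapes the
stage-1 posterior is prior-dominated, so desk-scale coefficient magnitudes
are indicative, not estimates.
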