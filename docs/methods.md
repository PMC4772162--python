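# Methods

`sdmstack` implements a stacked species-distribution-modeling workflow for
presence-only occurrence data on a regular lon/lat grid: collinearity
pruning and collection-bias diagnostics, maximum-entropy SDMs with
sample-size-dependent feature classes, a bias-corrected null-model
significance test for AUC, thresholded stacking into presence/absence and
richness, richness-driver analysis (trend surface, variation partitioning,
stepwise regression, Moran's I), beta-sim/UPGMA bioregionalization with an
indicator-species criterion for the number of regions, and relative
environmental turnover (NMDS, vector fitting, Getis-Ord Gi*). A synthetic
virtual-species world with known truth backs the test suite.

## Data model

The domain is a lattice of square cells (edge in arc-minutes; 10 by
default) with a boolean inside-mask; cells are half-open intervals with
the origin at the lower-left corner, so every coordinate maps to exactly
one cell. All containers are indexed by the contiguous ids of inside
cells. Occurrences are deduplicated to distinct (species, cell) pairs — a
"record" is one occupied cell — and species in fewer than `min_cells`
(default 5) distinct cells are dropped. Environmental rasters (ESRI ASCII
grid) are resampled to the analysis grid by mean aggregation for
continuous layers and nearest-neighbour for categorical ones, declared per
layer; cells left with a missing value in any layer are excluded from the
domain with a logged count.

## Predictor handling

Collinear predictors are pruned greedily in a user-declared priority order
(the "ecologically most meaningful first" ranking made explicit and
reproducible): a predictor is dropped when its Spearman |rho| with an
already-kept predictor reaches `rho_max` (default 0.75); survivors are
pairwise below the cutoff and the report names each dropped predictor's
triggering partner.

Collection bias is diagnosed per predictor with a Pearson chi-square over
`n_bins` (default 10) equal-interval bins of the domain-wide value range:
expected counts follow the domain's bin proportions, observed counts come
from the collection localities. Domain-empty bins are merged into their
nearest non-empty neighbour (df reduced accordingly) so expected counts
are never zero. The statistic's multinomial null is exact when collection
visits are counted with multiplicity; applied to deduplicated locality
sets from a small domain it is mildly conservative (a finite-population
effect), which only makes bias flags harder, not easier, to earn.

## Maximum-entropy SDMs

The MaxEnt model is implemented directly as its convex dual: an
L1-penalized log-linear density over background cells (all domain cells by
default), maximizing the penalized likelihood of the presence cells. The
optimizer is L-BFGS-B on the positive/negative split of the coefficients,
which handles the non-smooth L1 term exactly at optimality; features are
standardized over the background for conditioning.

Feature classes follow record count: 5-10 linear, 11-14 quadratic, >= 15
hinge (the two ranges quoted in common guidance overlap at 10 and omit 15;
this resolution covers all counts with minimal change). Hinge expansions
use 10 forward and 10 reverse hinges per predictor with knots at equally
spaced background quantiles. The per-feature penalty is
`reg_mult * base(n) * sd_presence / sqrt(n)` with a tabulated
sample-size-dependent base multiplier (`DEFAULT_BETA_TABLE`), a config
artifact in the spirit of common MaxEnt defaults — no parity with any
particular MaxEnt build is claimed, and none is needed: all downstream
thresholding is rank-based. Continuous suitability uses the complementary
log-log transform `1 - exp(-exp(H) q(x))` (H the entropy of the fitted
density over the background), a monotone map to [0, 1].

Model discrimination is the rank (Mann-Whitney) AUC of presences against
background with ties counted half; background may contain the presences
(pseudo-absence contract), and constant suitability scores 0.5.

## Null-model significance

Presence-only AUC has no absolute yardstick and biased collecting inflates
it, so each species' AUC is referred to a null distribution built by
refitting SDMs to `n_records` cells drawn uniformly without replacement
from the observed collection localities only (1,000 replicates by
default), with the same feature rule, background and penalties. All
species with equal record counts share one cached null distribution;
replicates are seeded from (seed, n_records, replicate) and recomputation
is bit-identical. The critical value is the nearest-rank 95th percentile
and significance requires strictly exceeding it (ties fail,
conservatively); the rank p-value is `(1 + #{null >= obs}) / (n_null + 1)`.

Because the cached critical value is itself one random draw, verdicts of
species sharing a null distribution are positively correlated; calibration
checks must add that covariance to the binomial variance (the acceptance
test does so explicitly).

## Thresholding and stacking

Species with 5-9 records use a ROC-derived threshold — sensitivity =
specificity by default, maximization of their sum as a config alternative;
species with >= 10 records use the fixed 10th percentile (linear
interpolation between order statistics) of suitability at the training
presences, giving ~10% training omission by construction. Presence means
suitability >= threshold. The stacked binary matrix (cells x species)
yields richness as row sums; species thresholded to zero cells are
retained but logged.

## Richness drivers

Spatial structure is the nine-term cubic trend surface of cell coordinates
(LON, LAT, their squares, cubes and cross terms), computed on centered,
range-scaled coordinates: the affine change leaves all partition fractions
invariant while keeping the cubic design well-conditioned. Variation
partitioning fits the environmental block E, the spatial block S and their
union by OLS and reports pure-env = R2a(E+S) - R2a(S), pure-space =
R2a(E+S) - R2a(E), shared = R2a(E) + R2a(S) - R2a(E+S), unexplained = 1 -
R2a(E+S); slightly negative fractions (adjusted-R2 artifact) are reported
as-is, and the four always sum to one exactly.

Influential predictors come from forward stepwise regression on z-scored
predictors (coefficients are betas): at each step the candidate with the
largest adjusted-R2 gain enters if its partial-F p-value is below
`alpha_enter` (default 0.05). Note the best of p candidates is tested, so
under pure noise the rate of any spurious entry is the family-wise
~`1-(1-alpha)^p`, not alpha — an inherent property of stepwise selection,
not a defect; reported t-values are final-model statistics. Residual
spatial autocorrelation is diagnosed with Moran's I under row-standardized
rook weights, expected value -1/(n-1), normal-approximation z and
two-sided p.

## Bioregionalization

Pairwise turnover is beta-sim, `min(b,c) / (min(b,c) + a)` (a shared, b/c
unique species), chosen for richness independence: surplus species in the
richer cell never change the value. Identical lists give 0, disjoint lists
1; one empty cell of a pair gives 1, two empty cells are excluded upstream
with a logged census. Cells are clustered by UPGMA (average linkage);
trees are cut into exactly k groups by merge order, which is robust to the
tied merge heights that saturated dissimilarities (many exact 1.0 values)
produce.

Indicator species analysis scores each species as specificity x fidelity x
100, maximized over clusters, with Monte-Carlo p-values from random label
permutations. The number of regions is chosen by minimizing the mean sum
of per-species indicator p-values over k = 2..k_max on repeated random
cell subsamples (defaults 2-30, five subsamples of 1,000 cells; all
desk-scalable), then cutting the full-matrix dendrogram at the winning k.
Summing raw p-values is the default; counting significant indicators is
available behind a flag.

## Relative environmental turnover

NMDS minimizes Kruskal stress-1 (monotone regression of configuration
distances on dissimilarities; 0 = perfect rank agreement) with 100 starts
by default: the first initialized from the classical Torgerson embedding —
which already solves exactly embeddable inputs — and the rest random,
seeded; the best configuration is centered and rotated to principal axes.
Convergence tolerance 1e-6, at most 500 iterations per start; a seeded
cell subsample (config) bounds the matrix size on large domains.

Environmental vectors are least-squares regressions of each standardized
predictor on the two axes; r2 is the variance fraction explained, the
direction is the unit coefficient vector, and the p-value permutes the
predictor's rows (999 permutations, reporting threshold P < 0.001 by
default). Each region's environmental distinctness is the Getis-Ord Gi*
z-value with binary region weights against the global mean and SD,
computed on a coarsened grid (2x by default, e.g. 10 -> 20 arc-minutes;
labels transfer by majority vote), flagged at |z| > 2. The sign of Gi*
equals the sign of (region mean - global mean), so one predictor can never
be a positive hotspot in every region.

## The synthetic world

The generator produces what the analyses assume, with truth retained:

- Environments: unit-variance Gaussian random fields low-pass filtered at
  a correlation length of 5 cells, plus a monotone latitudinal
  ("temperature-like") and longitudinal ("precipitation-like") gradient;
  optional near-duplicate columns exercise pruning.
- Species: Gaussian niches on 1-3 random predictors centered on the
  predictor values of a real cell; niche width is bisected per species
  until realized prevalence (cells with suitability > 0.5) lands in the
  requested range (default 5-25%).
- Regions: k contiguous blocks (Voronoi cells of k-means on cell centers);
  non-cosmopolitan species are dealt round-robin to regional pools and
  damped outside their home region with an e-folding edge of
  1/turnover_sharpness cells.
- Collecting: accessibility weights from a few random road corridors
  (dilated lines plus a floor); each visit event picks a cell by
  weight^bias_strength and a uniform species and keeps a record with
  probability equal to true suitability (detection = suitability, no false
  presences). `effort` is the expected number of kept records; localities
  are cells holding at least one record.

Default desk scale is a 40 x 30 grid (1,200 cells), 8 predictors, 200
species and 5,000 expected records, which spans the sparse (5-10),
intermediate (11-14) and rich (>= 15) record regimes. What the generator
does not emulate: taxonomic error, temporal collecting dynamics,
phylogenetic niche structure, detection differing from suitability, and
occupancy that is not a function of the supplied predictors — so passing
recovery tests shows the machinery is correct under its own assumptions,
not that real floras satisfy them.

## Numerical choices and edge cases

- Percentiles: thresholds use linear interpolation between order
  statistics; the null-model critical value uses nearest rank
  (conservative, deterministic).
- Ties: AUC counts ties half; threshold candidates pick the smallest value
  achieving the optimum; UPGMA tie-breaks are scipy's deterministic merge
  order, and tree cuts are by merge order.
- Degenerate inputs: constant predictors are dropped from features, flagged
  untestable in the bias test, and given r2 = 0 / p = 1 in envfit;
  constant values make Moran's I and Gi* undefined (errors); rank-deficient
  regression designs fall back to pseudo-inverse ranks.
- Determinism: every stochastic step takes an explicit seed; run
  manifests record the seed and a config hash, and resuming over a
  mismatched manifest is refused.

## Problem sizes used in the shipped checks

The test suite runs desk-scale worlds (up to 40 x 30 cells, <= 200
species); the null-model calibration check uses three replicates of 100
species with 199 null fits per record count 5-14, and regionalization
recovery uses a four-region world with 200-cell subsamples. These sizes
were chosen to exercise every code path at minutes scale; all are
configurable upward.
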