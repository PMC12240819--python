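# Methods

This note documents the models, conventions and design choices behind
`coretrans`, and what its synthetic benchmarks do and do not establish.

## Bioregion delineation

Presences define an unweighted bipartite network (cells and species as the
two node classes; presence/absence projection, no link weights). Community
detection uses the map equation: the `mapeq` backend calls the Infomap
implementation bundled with `python-igraph`, running `n_trials` independent
seeded searches and keeping the partition with the lowest codelength (ties
to the earliest run). Two-level partitions only.

The package includes its own codelength evaluator
(`map_equation_codelength`) so that alternative backends are comparable on
the same objective: node visit rates are PageRank probabilities with
uniform teleportation at rate 0.15 and module exit flow combines
teleportation out of the module with link flow across its boundary. This is
the same flow model as the igraph backend; the test suite asserts agreement
with igraph's reported codelength to 1e-6 on shared partitions. The
`components` backend (connected components) is exact for landscapes without
cross-region links, and the `truth` backend injects labels for oracle
tests.

Modules are excluded — flagged, never silently dropped — when any of the
four aspects would be undefined on them: no cells, no species, all cells
with identical within-module richness, or all species with identical
within-module occupancy. Cells of excluded modules do not enter the
clustering feature matrix, but their presences still count toward biota
overlap of other cells (they are real presences of non-characteristic
species).

## Cell and species aspects

The four aspects follow the within-module degree / among-module
connectivity scheme of bipartite network cartography (see README for the
formulas). Two conventions the formulas leave open are fixed here and
surfaced in the API:

- **Standard deviation**: sample convention (n−1 denominator) by default,
  matching the default of the statistical environments these analyses are
  usually run in; `ddof=0` switches to the population convention.
- **Median of an even-length set**: midpoint of the two central values.

A cell with no present characteristic species has no median-based aspects;
it is returned with `valid=False` and logged, not imputed. Within every
retained module the relative-richness values have mean 0 and sample s.d. 1
exactly; this and the complete set of formulas are enforced against a
brute-force per-node recomputation on random graphs.

## Sector clustering

Features are the four aspects, column-standardized over the rows being
clustered. k-means uses seeded random centroid initialization with
independent restart streams derived from the master seed; the best restart
by GoF (weighted between-cluster over total sum of squares) is kept.
Weights default to uniform; `weight_by_taxon` weights each cell by the
inverse cell count of its taxon, an optional sensitivity variant.

The per-taxon number of clusters comes from a continuous two-segment
piecewise-linear fit to the (k, GoF) curve: every interior k is tried as
the breakpoint, the model has three free parameters (shared value at the
breakpoint, two slopes), and the breakpoint minimizing the residual
standard error wins, ties to the smallest k. The general k maximizes the
across-taxa mean AMI between the joint partition (restricted to each taxon)
and the taxon-specific partitions, ties again to the smaller k. AMI is
scikit-learn's `adjusted_mutual_info_score` (arithmetic normalization).

Sectors of the selected partition are renumbered by decreasing centroid
relative richness. This gives figures and recovery tests a canonical
core→transition ordering; it is a labelling convention, not an extra
inference step.

## Adjacency tests

Neighbourhoods default to queen (8 neighbours) on the regular grid, with
rook available; each adjacent cell pair contributes one instance in each
direction. Counts are per bioregion; for a directed pair (A, B), n counts
all cross-sector neighbour instances from A's cells and x those landing in
B. The null probability stays 1/6 globally, also in regions with fewer than
seven sectors present.

The decision rule is the **exact one-sided binomial test**. The
continuity-corrected normal-approximation test (the behaviour of R's
`prop.test`, available as `method="score"`) flips the accept/reject
decision relative to the exact tail at 31 (n, x) combinations with
n ≤ 200 at α = 0.05 (e.g., n=35, x=10: 0.048 vs 0.055), so the exact test
is the default; the suite verifies its decisions against independently
computed rational-arithmetic tails over that whole range. Directions with
n ≤ 30 are untested ("insufficient neighbours"); a pair is significant when
either tested direction rejects at α = 0.05. Because a pair unions two
α-level tests, its nominal null level lies between α and 2α; the
calibration suite checks the directional rate stays at or below α and the
pair rate below 2α under shuffled labels.

## Environment models

Multinomial (softmax) regression of sector on covariates, fitted by
maximum likelihood (statsmodels `MNLogit`, BFGS, up to 500 iterations),
with covariates standardized internally and the largest sector as the
reference class. The null model is intercept-only, whose log-likelihood has
the closed form n·Σf·log f. AICc uses k = (K−1)(p+1) parameters and n =
cells; evidence requires AICc(null) − AICc(model) > 10, a deliberately
conservative bar (its false-positive rate on pure-noise covariates is
far below 5%). McFadden's pseudo-R² = 1 − lnL/lnL₀. Eligibility mirrors
the sampling safeguards of the analysis design: only sectors with more
than 15 cells enter, and a region qualifies only if at least two such
sectors jointly cover ≥ 90% of it. Non-convergent fits are flagged and
excluded from summaries with a log entry. Spatial-autocorrelation
corrections are out of scope.

## Beta-diversity partition

The multi-site Sørensen family: with S_i the site richnesses, S_T the
pooled richness and b_ij the one-way differences, β_SIM = Σmin/(ΣS_i − S_T
+ Σmin), β_SOR = (Σmin + Σmax)/(2(ΣS_i − S_T) + Σmin + Σmax), β_SNE =
β_SOR − β_SIM, sums over unordered pairs. Species absent from every site
are dropped first; identical sites give β_SOR = 0 and a *missing*
nestedness ratio (never 0 or 1). Implementation is checked against frozen
outputs of R `vegan::nestedbetasor` and an independent pairwise set-algebra
oracle, with additivity exact to 1e-12.

Sites are the sectors of one bioregion with presences pooled over each
sector's cells; characteristic species and non-characteristic species are
analysed separately, the latter once per region of origin.

## Richness decomposition and core test

Cell richness S is regressed (weighted least squares) on the regional pool
size (distinct characteristic species of the cell's region) and the
region-centred characteristic and non-characteristic richness. Weights are
the inverse bioregion size, normalized to sum to the number of cells, so
`weighting="none"` equals the all-equal-weights run exactly. Individual
fractions are R²(full) − R²(without the focal variable) using plain
(weighted) R², which keeps the fractions provably non-negative for nested
least-squares models — the reason adjusted R² is not used for the
partition. A constant predictor (e.g., pool size with one region) yields a
missing fraction with a reason.

The core-richness randomization permutes sector labels within a region
(preserving each sector's cell count), recomputing the pooled
characteristic richness of the core cells; p = (1 + #{null ≥ observed}) /
(n_perm + 1), never exactly zero. The default core is the prefix of the
richness-ordered sectors whose coverage is closest to 30% of the region's
cells, overridable per call.

## The synthetic landscape

The generator emulates the statistical structure of rasterized range-map
data; it is not a mechanistic simulation, and no published quantitative
generative model exists for it, so all distributional choices are this
package's own. Defaults (the reference conditions used by the test suite
and `scripts/acceptance.py`):

- 60×60 lattice tiled by 4 rectangular regions (contiguity guaranteed;
  a Voronoi mode gives irregular borders), 200 species per region,
  hotspot at each region's centre.
- Range-centroid density decays with distance from the hotspot at rate
  `hotspot_concentration = 8` (distance normalized to the region radius).
- Range sizes are log-normal with median 300 cells and σ = 0.5 — at the
  median a characteristic species occupies about a third of its 900-cell
  region. Sizes are rank-coupled to centroid distance (noise 0.15) so
  outer-seated species are the widespread ones; ranges are Chebyshev discs
  clipped to the region, matching queen contiguity.
- `permeability = 0.3`: a boundary-touching species spills into the
  neighbouring region with probability scaled logistic-in-range-size
  (widespread species spill preferentially), to a depth of at most 6
  cells. All random draws are taken whether or not used, so landscapes at
  different permeability but the same seed are coupled monotonically.
- Covariates = region-specific mean (s.d. 6 across regions) + 4·core_rank
  + unit Gaussian noise, giving regions distinct envelopes and concentric
  layers distinct conditions.

These values were fixed once, before the acceptance suite was written, so
that the planted regions are what the method is designed to detect:
cohesive network communities with the four core-to-transition gradients.
With substantially smaller or looser ranges the map equation *correctly*
prefers splitting a planted region into core and periphery submodules (the
split has lower codelength than the planted truth) — a property of such
landscapes, not an implementation artefact, and the reason range sizes are
generous relative to region size.

**What passing tests do and do not show.** The generator plants smooth
monotone gradients, rectangular contiguous regions, equal pool sizes and
isotropic noise; real data have irregular region shapes and sizes, range
cohesion failures, sampling artefacts and spatial autocorrelation, none of
which are emulated. Recovery results (e.g., sector/core-rank Spearman ≥
0.8) therefore validate the pipeline's correctness, not its power on real
data. One known desk-scale degeneracy: because every synthetic species is
relatively widespread, any random ~30% of a region's cells covers
essentially the whole pool, so the core-richness randomization saturates
(observed = null maximum, p ≈ 1) on the default landscape. The test's
mechanics are instead validated on constructed fixtures with narrow-ranged
species and by its null calibration (p approximately uniform under random
labels).

## Problem sizes and determinism

The default test suite and the acceptance script run the full pipeline at
the reference scale (3,600 cells, 800 species, ~270k presences) with 8
map-equation trials and 50 k-means restarts, and scaled-down landscapes
(24×24, 60 species/region, proportionally smaller ranges) for unit tests —
sizes at which the best found codelength is already stable (50 trials find
nothing better at checked seeds). Every stochastic operation takes an
explicit seed; the pipeline derives per-stage seeds from a single master
seed via `numpy.random.SeedSequence.spawn`, and byte-identical outputs
under a repeated seed are asserted in the suite.

## Known limitations

- Two-level partitions only; no hierarchical (multilevel) bioregions.
- Binary presences; weighted links are out of scope.
- Environmental models ignore spatial autocorrelation in residuals.
- The GeoJSON export draws cells as axis-aligned squares with a constant
  km-to-degree conversion — visualization only, no analysis depends on it.
- Pairwise (two-site) beta-diversity indices beyond the multi-site sums,
  and abundance-based variants, are not provided.
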