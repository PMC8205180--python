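# Methods

`phytoreg` implements a quantitative biogeographic-regionalization workflow:
species occurrence records are gridded, compositional turnover between grid
cells is measured with the beta-Simpson index, cells are clustered into
phytogeographic districts, the districts are tested and ordinated, and their
environmental correlates are identified by constrained ordination and vector
fitting. This note records the models, the defaults and their units, the
numerical conventions, and what the synthetic landscape does and does not
emulate.

## Turnover

For two cells with species sets of overlap `a` and unique counts `b`, `c`,

    betaSim = 1 − a / (a + min(b, c))

Using `min(b, c)` removes the effect of richness imbalance: a cell whose
assemblage is nested in another's scores 0, so the index isolates true
spatial replacement. Values near 0 mean most taxa are shared; above ~0.8,
almost none. Degenerate inputs: a pair of empty sets is undefined (error);
if exactly one set is empty the pair is treated as nested (0), though
neither case can occur for retained cells, which always hold at least one
species. The matrix is computed by incidence linear algebra
(`a = M Mᵀ`) and checked in the tests against an explicit set-algebra
oracle; it is stored as a scikit-bio `DistanceMatrix`, which enforces
symmetry and a zero diagonal.

## Gridding and the minimum-record filter

Records are binned into square cells (default 0.25°, the resolution of the
original workflow) that are half-open `[edge, edge + size)` with a
lower-left origin — edge handling is rarely stated in the literature, so it
is fixed here explicitly. Cells with fewer than `min_records` (default 5)
records are excluded, because tiny samples distort dissimilarities; their
records are folded into a neighbouring retained cell. The receiver is the
retained cell in the smallest Chebyshev ring (queen adjacency, expanding up
to `search_radius = 2`) with the most records, ties broken by lowest cell
id; excluded cells are processed in ascending record-count order against
the *original* retained set, which makes the outcome independent of
processing order. Excluded cells with no retained neighbour in range are
dropped with a warning (or raise, configurably) and logged, so the record
total is always auditable. Species names are whitespace-normalized and
lower-cased; no synonym resolution is attempted.

## Districts: WPGMA, consolidation, MRPP

WPGMA (McQuitty linkage) merges the closest pair of clusters and sets the
new cluster's distance to any third cluster to the plain mean of the two
merged clusters' distances, so each merged *cluster* — not each leaf —
contributes equally. Minimum search ties break on the lexicographically
smallest cluster-id pair for cross-platform determinism. Cutting the tree
at `k_groups` (default 8) typically yields a few large groups plus
scattered minor ones; consolidation keeps the `k_final` (default 2) largest
groups as districts and relabels each minor-group cell to the major
district it joins at the lowest cophenetic height. Districts are named
"A", "B", … in decreasing founding-group size; the name is arbitrary, and
downstream comparisons to planted truth align labels by majority overlap.

MRPP tests whether within-district mean dissimilarity is smaller than
chance: `δ = Σ_g (n_g/N) ξ_g` with `ξ_g` the mean pairwise within-group
dissimilarity, group weights `n_g/N` (the common default), a one-sided
permutation null that shuffles labels holding group sizes fixed, p =
(#{δ_perm ≤ δ_obs} + 1)/(P + 1) with P = 999 by default, and chance-
corrected agreement `A = 1 − δ_obs/mean(δ_perm)`. The implementation is
cross-checked against R's vegan in the test suite.

## Ordination

NMDS minimizes Kruskal stress-1,
`sqrt(Σ(d − d̂)² / Σ d²)`, over monotone transformations of the
dissimilarities. Each restart alternates an isotonic-regression fit of the
disparities (primary tie handling: tied dissimilarities are pre-ordered by
current configuration distance) with a Guttman majorization step; the step
is accepted only if stress does not increase, halving otherwise, so the
stress trace is non-increasing by construction. Convergence: relative
stress change < 1e-7 or 500 iterations; best of 20 random starts plus one
classical-scaling (Torgerson) start. Stress-1 is scale- and
rotation-invariant, so the final configuration is fixed by convention:
distances rescaled to the dissimilarities' RMS magnitude, centered, rotated
to principal axes, each axis signed so its largest-magnitude score is
positive. For mapping, axis signs are additionally flipped so the first
district in label order has non-negative mean score, making exports
invariant to global sign flips. Stress quality labels: ≤ 0.1 excellent,
≤ 0.2 good, < 0.3 fair, ≥ 0.3 poor.

## Environmental predictors

Pixel tables are averaged into cells under the same half-open rule used for
records. Collinear variables are pruned greedily: while any pair exceeds
|Pearson r| > 0.8 (configurable), the worst pair's member with the larger
mean absolute correlation to the remaining variables is dropped, each drop
logged with the triggering pair. Both the incidence matrix (response) and
the surviving predictors are z-scored (sample sd, n − 1); z-scoring binary
incidence columns is unusual but is the convention this workflow follows,
standardizing response and predictors to one scale.

RDA regresses every response column on the predictors; the canonical
variance is the total variance of fitted values and the proportion
explained is `tr(Ŷ'Ŷ)/tr(Y'Y)`. Forward selection ranks each unused
candidate by a Gaussian AIC of the multivariate fit,
`n·ln(RSS/n) + 2(p + 1)` with RSS summed over response columns — a ranking
statistic in the spirit of stepwise-RDA tables, not an absolute scale. The
best candidate is admitted if its marginal pseudo-F,
`ΔESS / (RSS_full/(n − p − 1))`, is significant under unrestricted row
permutation of the response (default P = 999, α = 0.05) *and* it lowers the
model AIC (the parsimony stop; disable `require_aic_improvement` to study
the permutation gate alone — with a single candidate that gate is exactly
calibrated, whereas best-of-m selection is deliberately greedy and
anti-conservative, as in any stepwise procedure).

## Vector fitting and tracks

`envfit` regresses each centered environmental variable on the ordination
axes; the normalized coefficient vector gives the direction cosines, r² the
variance explained, and significance comes from permuting the variable
across cells (the scores stay fixed), the standard post-hoc vector-fitting
null. Exclusive species are those whose every occupied cell lies in one
district; their collecting points are linked by a minimum spanning tree
over great-circle (haversine, R = 6371 km) distances — geographic distance
is the only defensible metric at sub-continental extent. Duplicate points
are collapsed and Prim's algorithm breaks ties by lowest point index after
lexicographic sorting, so the tree is deterministic.

## Synthetic landscape

The generator plants the structure the analysis assumes, so every stage is
testable without any database access:

* **Relief.** Elevation = a west-to-east linear ramp (150–1400 m) plus a
  Gaussian random field (sd 120 m, smoothed over 1.5 cells). District A
  ("upper") is every cell at or above 750 m, district B below; the ramp
  guarantees two contiguous districts. Default extent is a 12 × 12 grid of
  0.25° cells.
* **Community.** 50 upper-exclusive, 10 lower-exclusive and 40 shared
  species — the strong exclusivity asymmetry of an upper vs a lower
  district, scaled down (~100 species / ~150 cells) so the pipeline runs in
  seconds; `PAPER_SCALE_COMMUNITY` (292/32/247 species) is the full-scale
  preset. Per-cell visit counts are Poisson with mean 20 (negative binomial
  with variance `mean·(1 + overdispersion)` when overdispersed); the
  literature gives no per-cell record-count distribution, so this is an
  assumption, flagged as such. Each visit records one species drawn from
  the cell's district-eligible pool with lognormal (σ = 1.2) relative
  abundances — a standard species-abundance shape that gives cells of the
  same district realistically overlapping common species — and is kept
  with probability `detection_prob` (default 1). With `effort_mean = 4`, a
  substantial fraction of cells receives fewer than five records,
  exercising the filter-and-merge path.
* **Environment.** Each layer is district-conditional Gaussian with
  optional spatial smoothing. Soil Ca (0.93 ± 0.49 vs 0.40 ± 0.16 mg) and
  Mg (0.29 ± 0.08 vs 0.32 ± 0.07 mg) use the reported upper/lower
  contrasts. Precipitation seasonality (CV 78 vs 88 %) and driest-quarter
  precipitation (38 vs 19 mm) are not reported per district anywhere, so
  realistic seasonally-dry-tropical-forest values were fixed once, with the
  lower district drier and more seasonal. Four `noise_*` layers with
  identical district distributions act as decoys for predictor selection.

What the generator does **not** emulate: taxonomic misidentification and
synonymy, georeferencing error, spatial autocorrelation of sampling effort,
within-district compositional gradients, and realistic species range
shapes (occupancy is exchangeable within a district). Passing the planted-
recovery tests therefore shows the pipeline recovers district structure of
the planted kind; it does not certify performance on real herbarium data,
whose biases are richer.

## Problem sizes and determinism

Every stochastic component takes an explicit integer seed
(`numpy.random.default_rng`); rerunning a configuration reproduces output
files byte for byte (CSV floats use fixed formats, GeoJSON coordinates
fixed precision). The test suite's simulation sizes — 1,000 MRPP
calibration replicates at P = 199, 500 envfit null replicates, 400
forward-selection null replicates at P = 99, 20 end-to-end driver-recovery
replicates at P = 199, brute-force MST enumeration at n = 7 — were chosen
as the smallest scales at which the binomial/KS acceptance bounds are
informative.

## Known limitations

* The AIC is a per-model ranking statistic; its absolute values are not
  comparable across software that aggregates multivariate likelihoods
  differently.
* MRPP group weights, the collinearity threshold, `k_groups`/`k_final` and
  the merge-receiver rule are documented conventions where the underlying
  methods literature is silent; all are exposed in configuration.
* NMDS is a local optimizer; the restart count trades runtime against the
  risk of local minima (the classical-scaling start makes embeddable
  inputs reliable).
* The stepwise admission p-values are not corrected for selection over
  candidates; treat the step table as exploratory ranking, as stepwise
  tables always are.
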