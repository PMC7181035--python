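# Methods

## Problem and model

The pipeline treats a city as a mosaic of fixed-size image tiles and asks
two questions: do the tiles fall into a small number of landscape types,
and do those types carry different population-health profiles? The first
is answered by unsupervised clustering of tile embeddings; the second by
categorical association statistics between cluster membership and
tile-level health indicators obtained by areal interpolation from census
tracts.

The health indicators are taken as given per tract (in practice,
model-based small-area prevalence estimates). No causal claim is implied
anywhere: the statistics quantify association between landscape cluster
and indicator levels, with tiles as the unit of analysis.

## Georeferencing conventions

All geometry lives in a projected metric coordinate system. Rasters carry
an axis-aligned world transform in the ESRI world-file convention: the
origin is the map coordinate of the **center** of the top-left pixel, the
pixel height is negative for north-up images, and rotation terms are
required to be zero (rotated or skewed rasters are out of scope, as is
reprojection). A tile at grid position (r, c) inherits the parent pixel
sizes and an origin shifted by a whole number of pixels, so any pixel's
map coordinate is identical whether computed through the tile or the
parent transform — this is tested exactly, not to a tolerance. Tile
footprints extend half a pixel beyond the border pixel centers, so the
footprints of adjacent tiles tile the plane without gaps.

GeoTIFF georeferencing is read from the ModelPixelScale and ModelTiepoint
tags (converting the corner-origin convention to center-origin); any
other raster format needs a 6-line world-file sidecar.

## Tiling and filtering

Grid dimensions use the ceiling rule on both axes, so edge tiles may
overhang the raster; they are zero-padded to full size, the padding is
excluded from the footprint and counted as white. At the published city
scale (23,972 × 23,892 px, 256-px tiles) this gives a 94 × 94 grid and
8836 tiles.

Two filters are applied conjunctively, which makes their order
irrelevant: the fraction of the footprint inside the city boundary must
be ≥ 0.9, and the fraction of white pixels ≤ 0.1. "White" is all three
channels ≥ 250 — the threshold is a design choice (the concept is
"unmapped area", which in practice is near-white after compression).
Filtering is monotone in both thresholds (property-tested).

## Areal interpolation

The tile-level indicator is the overlap-area-weighted mean of tract
values, with the weight of tract *j* equal to the fraction of the tile
footprint covered by that tract. Division by Σwⱼ (rather than by 1) means
a tile partially outside all tracts is estimated from the covered part
only. Tracts with a missing value are dropped and the weights
renormalized over the remainder; an estimate exists iff at least one
contributing tract has a value. Consequences, all tested: the estimate is
a convex combination of contributing values; subdividing tracts without
changing values never changes any estimate (refinement invariance); a
constant field is reproduced exactly. Weights are purely areal — no
population weighting — which is a stated limitation of the approach, not
an oversight.

## Embedding and extractor selection

Extractors are pluggable; the bundled baseline computes, per tile:
16-bin intensity histograms per channel (48 values), the greenness
fraction, and the mean and standard deviation of the gradient-magnitude
field of the unit-scaled gray image (51 dimensions total). Greenness is
the fraction of pixels with G strictly greater than R and B and G ≥ 64 —
the strict dominance excludes gray, the floor excludes dark noise. Every
component is a function of the multiset of pixel values or gradient
magnitudes (the gradient summaries are accumulated in sorted order), so
the features are bit-identical under 90° rotations. The gradient
summaries are computed on gray/255 so that all 51 features share a
roughly common scale; features enter k-means unscaled, so grossly
mismatched scales would let one feature dominate the Euclidean geometry.

Candidate extractors are compared by embedding all tiles, projecting to
2-D with t-SNE (perplexity 30 capped at (n−1)/3, 1000 iterations, fixed
seed, PCA initialization), taking the top 10% of tiles by greenness (at
least 2), and scoring the sum of squared distances of their 2-D
coordinates to their centroid. The lowest SSE wins; ties break to the
earlier candidate. The quantile, the t-SNE settings, and the use of the
2-D map (rather than the raw feature space) are design choices; all are
configurable and recorded in output metadata. Greenness is used only for
extractor comparison and for the final relabeling of clusters, never as a
clustering feature beyond its role as one of the 51 baseline components.

## Clustering

For each K in 2…6, k-means with Euclidean distance is run 10 times from
independently seeded starts and the lowest-inertia fit kept ("best of
reruns"); the kept fit is scored by the mean silhouette over the full
sample. The chosen K maximizes the silhouette, ties going to the smaller
K. Cluster ids are relabeled 1…K by descending mean greenness of their
members, making "cluster 1 = greenest" a deterministic convention rather
than an artifact of initialization.

The rotation-invariance validation embeds selected tiles together with
one randomly rotated (90/180/270°, seeded) copy each, hierarchically
clusters them (average linkage, Euclidean), and reports the fraction of
originals whose first dendrogram merge is with their own copy. For an
exactly rotation-invariant extractor the copy sits at distance zero, so
the fraction is 1 by construction; the check is informative for
extractors that are only approximately invariant.

## Association statistics

Tertiles are cut at the empirical 1/3 and 2/3 quantiles; observations are
assigned by stable rank so counts differ by at most one even with ties.
The K×3 cluster-by-tertile table is tested with Pearson's chi-squared
((K−1)·2 degrees of freedom, no continuity correction); type-I error at
the 5% level is simulation-tested to lie in [0.03, 0.07] under the null.

Multinomial logistic regression uses cluster 1 (greenest) as the baseline
outcome. Reported quantities per contrast and term: the coefficient, its
exponential (odds ratio), the standard error from the observed
information, and a Wald p-value; AIC = 2·k − 2·logLik. Tertile-coded
predictors enter as two dummies with tertile 1 as reference. Univariate
runs delete rows listwise per variable; the multivariate run deletes rows
missing any candidate variable once, up front. No multiple-testing
correction is applied; raw p-values and −log₁₀ p are reported.

Fitting is Newton–Raphson with a BFGS fallback. Convergence is judged by
the relative log-likelihood improvement falling below 1e-8 — a criterion
that is *satisfiable under quasi-complete separation*, where the MLE lies
at infinity but the likelihood plateaus. This mirrors the behavior of the
standard R fitting route for this model and keeps strongly separated
synthetic data analyzable; in that regime odds ratios are extreme and
Wald standard errors enormous (computed from the pseudo-inverse of the
information matrix when it is singular), which is the honest description
of a separated fit. A fit that still improves after the continuation
budget is returned with `converged = False` and the stepwise procedure
refuses to start from it.

Backward stepwise AIC removes, at each step, the term *group* (all dummy
columns of one variable together) whose removal most decreases AIC,
stopping when no removal helps; the accepted-step AIC sequence is
strictly decreasing by construction. Group-wise removal is a design
choice; removing dummies individually would allow a variable to survive
with half its coding.

## Agreement analysis

The confusion matrix has human categories as rows and machine clusters as
columns, with per-row TPR/FNR and per-column PPV/FDR (undefined margins
reported as NaN). Cohen's κ = (pₒ − pₑ)/(1 − pₑ); the maximum attainable
κ replaces pₒ with Σᵢ min(rowᵢ, colᵢ)/n, the best diagonal under the
observed margins. The test against chance is one-sided with the
large-sample null standard error. Under simulated independent raters the
mean κ is within ±0.02 of zero (tested over 1000 replicates). Verbal
bands are the conventional half-open intervals (0.4–0.6 moderate,
0.6–0.8 substantial, …), with 1.0 in the top band.

When several raters label a tile, the modal category is used, ties
breaking to the lowest category id; the rating instrument's fifth option
("unknown/other") is excluded before pooling. Both rules are recorded in
output metadata.

## Synthetic city generator

The generator emulates the four inputs of a real analysis. Landscape
archetypes: 1 green, 2 small houses, 3 industrial, 4 large buildings,
each a procedural texture (base color + noise + palette blocks whose
count targets a fixed coverage, with per-block color jitter so tiles of
one archetype form a single unimodal cloud in feature space). Archetypes
are laid out in contiguous tile-aligned patches (nearest-seed regions),
so census tracts have a meaningful dominant archetype. Tracts are a
tile-aligned rectangular grid merged down to the requested count, giving
an exact partition of the boundary and exactly computable overlap
weights. Indicator values are Normal(mean of dominant archetype, sd);
the defaults plant a strict monotone gradient in `phys_unhealthy_days`
(means 2.5, 3.5, 4.5, 5.5; sd 0.7, chosen so adjacent archetypes overlap
the way neighboring neighborhood types do) plus a decreasing screening
indicator and an increasing obesity indicator. Missing values can be
injected at a configurable rate (default 0). Everything derives from a
single seed and is bit-reproducible.

What the generator does **not** emulate: visual realism or real aerial
radiometry; spatial autocorrelation of indicators beyond the archetype
gradient; population density (so areal weights are exercised, population
weighting is not); rater psychology (simulated raters err uniformly).
Passing tests therefore demonstrate the machinery — geometry, estimator
algebra, model selection, inference calibration — not performance on real
imagery, where the embedding quality of a pre-trained CNN would dominate.

## Problem sizes and numerical choices

Tests and the acceptance script run the synthetic city at 32-px tiles on
a 20×20 grid (400 tiles, 60 tracts); the geometry and statistics are
size-invariant, and these sizes keep the full suite fast while leaving
every code path identical to a full-scale run. Simulation-based checks
use 1000 replicates (chi-squared calibration, null κ), n = 5000
(multinomial parameter recovery, tolerance 0.15 on coefficients), and 20
seeded runs of n = 2000 (stepwise selection). k-means rerun seeds are
drawn from a single generator per grid search; t-SNE seeds are explicit
everywhere. Degenerate inputs fail loudly: constant vectors cannot be
discretized, all-identical feature rows have no silhouette, zero-area
footprints and zero contingency margins raise, and κ is undefined when
chance agreement is 1.
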