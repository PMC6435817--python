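# Methods

This note documents the models, estimators and numerical choices behind
`agrocore`, and what the synthetic-data tests do and do not establish.

## Study design assumed by the pipeline

The pipeline targets paired-site agricultural surveys: maize (dryland) and
rice (wetland) fields sampled in adjacent pairs (< 5 km apart) along a
latitudinal mean-annual-temperature (MAT) gradient with an independent
soil-pH gradient.  Habitats are analyzed separately everywhere except the
enrichment stage, which consumes the complete maize–rice pairs.  All
analyses run on a single rarefied count table; rarefaction draws each
sample down to a fixed depth without replacement (multivariate
hypergeometric), one draw per sample, dropping samples below the depth.
The configuration default is the 27,812-read depth of the survey the
pipeline emulates; synthetic runs use 10,000 reads against simulated
depths centred on 20,000.

## Core microbiota and ecological clusters

An OTU is core when (i) it ranks in the top `ceil(0.10 · n_OTUs)` by mean
relative abundance across all samples of the habitat (ties broken by OTU
id so the rule is deterministic), and (ii) its occupancy — the fraction
of samples where it is present — strictly exceeds 0.80 (a flag switches
to ≥).  Both thresholds are monotone: raising either never adds a member.

Cluster assignment computes Spearman ρ of each core OTU's relative
abundance against pH and MAT.  The candidate set is the drivers with
p < 0.05; the driver with larger |ρ| is assigned (pH wins an exact tie, a
choice that matters only on degenerate data), and sign(ρ) sets high/low.
Because Spearman is rank-based, assignment is invariant to any strictly
monotone transform of a driver.

## Multinutrient cycling index

Eight available-nutrient variables (DOC, AN, NO₃, NH₄, AP, AK, AS, AFe)
are each optionally log-transformed, Z-scored with the sample (n−1)
standard deviation, and averaged per sample.  "Log-transformed as needed"
is operationalized as: natural log when the variable's sample skewness
exceeds 1 (bias-corrected skewness; threshold configurable; explicit
per-variable overrides accepted).  The decision is a deterministic
function of the data and is recorded with the result.  Samples missing
values average over the available standardized variables when at least 6
of 8 are present, otherwise their index is NaN.  The index is exactly
invariant to per-variable affine rescaling and to variable order.

## Distance-based statistics

Bray–Curtis dissimilarity is computed on row-normalized relative
abundances.  ANOSIM uses R = (mean between-group rank − mean within-group
rank)/(M/2) with M = n(n−1)/2.  PERMANOVA Gower-centres the squared
distance matrix and partitions it by sequential (type-I) sums of squares
over the model terms, so continuous covariates are supported; the test
permutes sample identities.  CAP performs principal-coordinate analysis
(axes with negative eigenvalues truncated by default; Lingoes correction
behind a flag), regresses the site scores on the constraints and
eigen-decomposes the fitted values; with a single constraint and a
Euclidean-embeddable distance matrix its pseudo-F equals PERMANOVA's.
All permutation p-values use (1 + #{null ≥ observed})/(1 + B) with an
explicit seed.

Redundancy reduction removes one member of every environmental-variable
pair with |Spearman ρ| above 0.6, greedily from the most correlated pair;
a priority list (default: keep pH, then MAT) decides the keeper, falling
back to removing the member with the larger mean |ρ| to the remaining
variables, with an alphabetical tie-break.  The distance-based linear
model standardizes predictors, adds at each forward step the candidate
with the largest conditional R², and gates entry on a Freedman–Lane
permutation test (the candidate's residuals on the selected set are
permuted) at α = 0.05 with 999 permutations by default.

Non-metric MDS minimizes Kruskal stress-1 by SMACOF majorization with
isotonic regression of the configuration distances on the dissimilarity
order, best of several starts (classical-scaling initialization first,
then random).  Stress-1 is scale-free, so the final configuration is
rescaled to the dissimilarity scale, then rotated to principal axes with
a positive-skew sign rule, making the axes deterministic given the seed —
a requirement for regressing on NMDS1/NMDS2 downstream.

## Co-occurrence networks

OTUs with mean relative abundance below 0.01% are removed first.  All
remaining pairs are tested with Spearman correlation (vectorized
rank-Pearson with the t approximation for n ≥ 10; the exact-permutation
primitive below that), and BH-FDR is applied over all pairs tested in the
build.  Edges require ρ > 0.6 (one-sided positive, per the construction
rule; an `absolute` flag thresholds |ρ|) and q < 0.01.

Topology: betweenness is shortest-path betweenness normalized within each
connected component; closeness is harmonic centrality divided by (n−1),
well-defined on disconnected graphs; eigenvector centrality is computed
on the largest component by power iteration and max-normalized to 1, with
zeros elsewhere; the clustering coefficient is the mean local clustering
with degree-< 2 nodes contributing 0; path length and diameter refer to
the largest component; modularity scores the partition found by greedy
modularity maximization (deterministic agglomeration).  Group contrasts
of node metrics use Wilcoxon rank-sum for two groups and Kruskal–Wallis
plus BH-corrected pairwise rank-sum tests with a compact letter display
for more.

## Enrichment

Per OTU, a paired t test of relative abundance across complete maize–rice
pairs; the statistic is mean(d)/(sd(d)/√n), and sd(d) = 0 (including
float-cancellation constant shifts) yields an NA flagged as
non-significant.  The default classifies at raw p < 0.05 — the
construction rule taken literally — with `fdr=True` recommended for
multiplicity control; classifications are verified with Kruskal–Wallis.
Classification is exactly antisymmetric under swapping habitat labels.

## Attribution

The regression random forest is built from scikit-learn decision trees
with explicit bootstrap bookkeeping (mtry = ⌈p/3⌉), so the out-of-bag
(OOB) set of every tree is known.  Importance is the accuracy convention:
the increase in OOB mean squared error when a predictor is permuted among
the OOB samples, averaged over trees.  Significance refits the forest on
response-permuted datasets and reports the null exceedance probability.
The figure-level convention is 5,000 trees; importance *rankings* are
stable far below that, and scaled-down forests (500 trees in the recovery
tests, 20 in the calibration study) preserve them.

LMG variance decomposition computes R² for every predictor subset (exact,
p ≤ 10) and averages each predictor's sequential contribution over all
orderings via the subset-weighting identity; shares are non-negative for
well-conditioned designs and sum to the full-model R² to numerical
precision.  Predictors are standardized internally (R² is invariant) and
exactly collinear designs are rejected, naming the aliased columns.
Class-level models select predictors by forward selection (adjusted R²
with a partial-F entry test at α = 0.05) before decomposition; shares
below 0.5% are reported as 0.

## Kriging

Coordinates are projected to planar kilometres by a local equirectangular
approximation (adequate at continental-survey extents; geodesic distances
are out of scope).  The empirical semivariogram is the Matheron
estimator, 15 bins to half the maximum pairwise distance by default.
Model fitting minimizes Cressie-weighted residuals (weights N_h/γ_model²)
over exponential, spherical and Gaussian forms with a deterministic
multistart over initial ranges; the lowest weighted SSE wins, with a
linear-with-sill fallback flagged on total failure.  Fitted ranges are
capped at twice the lag window: longer ranges are not identifiable from
the data and the cap keeps the nugget/sill decomposition honest.

Ordinary kriging solves the constrained system with the Lagrange
multiplier; weights sum to 1 by construction, and with a zero nugget the
predictor interpolates the data exactly.  Duplicate coordinates (paired
sites) are jittered by 10⁻⁶ km with a warning.  Leave-one-out
cross-validation keeps the variogram fixed from the full fit and reports
the Pearson correlation between LOO predictions and observations.  Two
degenerate behaviors are worth knowing: on a spatially unstructured
(pure-nugget) field the LOO predictor is a weighted mean of the other
sites and therefore anti-correlates weakly with the held-out value (of
order −1/√n; exactly −1 with equal weights, a case detected and reported
as r = 0 with a warning), so "no skill" appears as a slightly negative r,
not exactly 0.  And from a single realization of ~200 points, the range
parameter of an exponential variogram is only weakly identified — the
fitted variogram *function* is reproducible, but (partial sill, range)
individually scatter by ±30–40%.

## Synthetic surveys and what passing tests show

The generator emulates the paired design: `n_sites` paired locations with
latitude-driven MAT (a − b·lat + noise), a longitude-driven pH gradient,
latitude-banded soil types, and per-pair coordinate jitter under 5 km.
Community counts are multinomial draws from log-linear expected
abundances: per-OTU log-normal baselines (core taxa high and tight,
non-core wide), signed log-linear niche responses to standardized pH or
MAT (a unimodal Gaussian response is available behind a flag), habitat
log-fold-changes on a subset of non-core OTUs, and correlated blocks
driven by a shared latent factor (latent within-block correlation 0.9)
whose members also share a niche driver — mirroring the observation that
co-occurring taxa share environmental preferences.  Effect sizes are
calibrated in units of the idiosyncratic log-abundance noise (σ = 0.5):
the default core niche slope of 1.0 per driver SD is a 2σ effect.

Composition is hierarchical: each sample assigns a stable share (~0.68,
matching the roughly two-thirds of sequences that core taxa carry in
surveys of this kind) to the core group and splits it within the group by
softmax of the latent log abundances, likewise for the non-core group.
This choice prevents group-level abundance swings from leaking
compositional correlation into unrelated taxa, so "independent" OTUs in
the truth really are uncorrelated targets for the network
false-positive checks.  Nutrients are coupled per habitat either to
realized Shannon diversity (alpha mode; maize default) or to the first
latent composition factor (beta mode; rice default), scaled into
realistic mg/kg-style units, four of the eight log-normal so the MNC
skewness rule engages.

Passing recovery tests therefore show that each stage detects the
structure it is designed for at realistic effect sizes and sample sizes —
not that real soil communities satisfy the generator's assumptions.  In
particular the generator draws independent multinomial counts (no
overdispersion beyond the log-normal layer), uses log-linear rather than
unimodal niche responses by default (matched to the Spearman-based
cluster assignment), and couples nutrients to diversity by explicit
construction; none of these are claims about field data.

## Problem sizes and defaults

Recovery tests run at the default design — 60 paired sites (120 samples),
400 OTUs, 40 planted core taxa, rarefaction to 10,000 reads — with 3–5
replicate surveys; the attribution contrast uses 50 replicates with
500-tree forests; permutation-test calibration uses 200 replicates of 199
permutations at n = 16–20 with 20-tree forests for the
response-permutation null.  These sizes were chosen so the full suite
doubles as a practical regression battery; the statistical properties
they check are size-free (calibration) or stated at the design's effect
sizes (recovery).
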