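# Methods

This note documents the models, numerical choices and limitations behind
the pipeline; it is the place to look when a default needs justifying.

## Niche-space reduction

**Gower dissimilarity.** For a pair of species within one niche dimension,
each quantitative trait contributes |xᵢ − xⱼ| / range (range taken over the
input table) and each binary trait a symmetric 0/1 mismatch; the
dissimilarity is the unweighted mean of the per-trait contributions.
Binary states are treated as equally informative (symmetric) because the
recoded habitat and defense flags are presence/absence of equal standing;
a Jaccard-style asymmetric option (`binary_mode="asymmetric"`) excludes
double-zero pairs from a trait's denominator for users whose binary traits
mark rare states. Quantitative traits with zero range carry no information
and are dropped with a warning rather than poisoning the mean with 0/0.
Life-history traits are not log-transformed by default; callers can
transform columns before building the table.

**PCoA.** Classical metric scaling: double-center −d²/2, eigendecompose,
order axes by descending eigenvalue, scale eigenvectors by √λ. Gower
dissimilarities are generally non-Euclidean, so negative eigenvalues can
occur; no Cailliez/Lingoes correction is applied, and variance percentages
are computed over the positive eigenvalues only. Eigenvector sign is
inherently arbitrary; every axis is oriented so the alphabetically first
species with a non-zero score is non-negative, which makes ordinations
reproducible across runs and platforms.

**PCA.** Performed on standardized columns (correlation matrix), because
the six functional variables are PCoA scores on unrelated scales; raw
covariance PCA is available via `standardize=False`. Per-axis variable
contributions are 100·loading² (unit-norm eigenvectors, so each axis sums
to 100). Correlations of variables with axis scores carry two-sided
p-values; variables contributing < 5% to an axis are reported as
not-tested (NaN), since a correlation with a negligible contributor is not
interpretable.

**KDE regions.** Gaussian KDE with the normal-reference (Silverman)
bandwidth on a regular grid (64 points per axis in 2-D, 32 in 3-D,
padded by three bandwidths). The L% region is the smallest grid
superlevel set whose threshold keeps at least L% of the sample points
inside — thresholds come from the sorted sample densities, so regions are
nested by construction and their coverage is exact on the sample, not the
grid. A plug-in bandwidth was not implemented: no downstream quantity
depends on the KDE beyond region membership, and the normal-reference rule
is adequate for delineating occupancy at these sample sizes.

## Hypervolume and null models

The occupied hypervolume is the convex hull (Qhull) of the n × 6 species
coordinates. Degenerate inputs (n ≤ d, affine rank deficiency) raise an
error instead of being jittered: silent perturbation would corrupt the
null distribution the volumes feed.

Null models: NM1 draws each axis independently uniform over the observed
min/max (the minimal reading of "uniform in the functional space"; an
inflated range would only make the test more liberal); NM2 independent
normal with observed mean and sd; NM3 permutes each observed column
independently, preserving marginals exactly while destroying correlation;
NM4 is multivariate normal with the observed mean vector and covariance
(non-positive-definite covariances are repaired by eigenvalue clipping,
with a warning). Each model consumes an independent substream of the seed,
so adding or removing models never shifts another model's replicates.

The test is one-tailed for a smaller observed volume — the scientific
hypothesis is constraint, not expansion — with the add-one convention
p = (1 + #{V_null ≤ V_obs})/(1 + R), R = 999 by default. The reported
"ratio" is the percent reduction 100·(V̄_null − V_obs)/V̄_null; a
per-replicate-mean alternative is exposed behind `ratio_mode`. Applied to
reference volumes 105.75 against a null mean of 1129.289 this formula
gives 90.6, matching published ratios of this type to within about 0.1.

Calibration (recomputed by the acceptance tests): under NM1's own
generative process the rejection rate at α = 0.05 stays within 0.05 ± 0.06
over 50 runs (the test is mildly conservative because the null's support
is estimated from the observed range); against equicorrelated normal data
(pairwise r = 0.8, n = 134) NM1–NM3 reject in ≥ 95% of runs.

## Functional groups

The label space is the fixed enumeration {SW, WF} × {AQ, F, C, T, S, A} ×
{D, N} — 24 labels regardless of the data. Published spellings vary
("SW-Aq-N", en-dashes); labels are normalized to canonical uppercase with
an alias map. Classification is the Cartesian product of a species'
foraging, habitat and activity sets, so a species' membership count is the
product of its set sizes. Family is carried as free text; no taxonomic
validation is attempted.

## Phylogenetic structure

**Correlation matrix.** C[i,j] is the shared root-to-MRCA branch length
divided by the geometric mean of the two root-to-tip depths (unit
diagonal); on an ultrametric tree this is shared depth / tree depth.
Cophenetic distances are computed by a vectorized postorder pass
(d(i,j) = depthᵢ + depthⱼ − 2·depth_MRCA), which is exact for arbitrary
rooted trees and fast enough for thousands of tips.

**PSV.** PSV = (n·tr(C) − ΣC)/(n(n−1)) over a group's submatrix, using the
correlation (unit-diagonal) form so branch-length units never enter:
1 for a star phylogeny, 0 when all pairwise correlations are 1, and 1 − c
for a pair with correlation c. Groups with fewer than two members are
excluded with a warning. The permutation null redraws, for every group
independently, a uniform same-sized subset of the pool (groups may share
species, mirroring observed multi-membership); verdicts use the empirical
α/2 and 1 − α/2 quantiles of R = 1000 replicate means.

**Fuzzy weighting and PCPS.** Phylogenetic similarity is
S = 1 − d/max(d) over the cophenetic distances — bounded, monotone, and
exactly the identity on a star tree; the shared-branch correlation is
available behind `similarity="shared-branch"`. Each species' similarity
row is standardized to sum 1 (matrix Q), so every species distributes one
unit of belonging across its phylogenetic neighborhood; matrix P is the
row-standardized group incidence composed with Q, hence row-stochastic.
Raw 0/1 incidence is used (not down-weighted by a species' number of
groups); with row standardization the alternative differs only by a
per-group factor. PCPS is the PCoA of square-rooted Bray–Curtis
dissimilarities between rows of P; axes explaining > 10% of positive
variance are retained. Species–axis correlations are plain Pearson
correlations of each species' column of P with the group scores across
groups, used to read which clades drive an axis.

## Synthetic data

The generator emulates the structure of a global lizard functional-trait
compilation: a deep basal divergence (two or more forced basal clades, as
between Gekkota and the remaining squamates), mixed binary/quantitative
trait blocks per niche dimension (default 18 binary + 24 quantitative
across the six dimensions, echoing the composition of real datasets),
phylogenetically conserved multi-state ecological attributes, and
multi-group membership from mixed strategies.

Trees are pure-birth (Yule) with depth normalized to 1 (ultrametric by
construction; tested to 1e−9 by root-to-tip path summation). With forced
basal clades, the basal splits occupy the first `basal_window` (default
0.05) of the depth, each clade's radiation the last `clade_depth_fraction`
(default 0.7), and the clade stems in between carry the shared history
that conservatism acts on.

Traits mix a Brownian-motion component (factorized from the tree's
correlation matrix) with iid noise as √c·BM + √(1−c)·ε, so the
conservatism dial c ∈ [0, 1] moves continuously from tree-independence to
pure Brownian evolution, with unit marginal variance throughout. Binary
traits threshold the latent variable at its empirical
(1 − prevalence)-quantile (prevalence defaults to 0.5; real prevalences
are unknown, so it is a parameter, not a constant). Group membership uses
a mixture draw: each member slot samples from the group's focal clade with
probability c, otherwise from the pool — monotone in the dial, clade-pure
at c = 1, uniform at c = 0. Note that a clade-pure group is monophyletic
only when it exhausts its clade; tests that need monophyly request
clade-sized groups.

All generators are pure functions of (config, seed); per-stage substreams
are derived by CRC-hashing the stage name into the seed sequence, so any
stage can be re-run independently without disturbing the others.

What passing tests on these data do **not** show: real trait tables have
missingness, measurement error, non-Gaussian trait distributions,
unbalanced clade sizes and non-ultrametric uncertainty, none of which the
generator produces. The calibration results (type-I error, power,
parameter recovery) certify the statistical machinery, not the fit of any
particular empirical dataset.

## Problem sizes and defaults

The analysis drivers use 96 species, R = 499 hull replicates and R = 999
PSV replicates — large enough for stable quantiles while keeping a full
run in minutes on a laptop core. The calibration studies in the acceptance
tests use n = 134 species in 6-D with R = 199 and 50 runs (hypervolume)
and 64 species with R = 199–999 and 20–200 runs (PSV), sizes at which the
empirical rates have standard errors well inside the asserted bands.

## Known limitations

- Convex hulls are driven by extreme observations; no probabilistic
  hypervolume is offered (in 6-D it would need far larger samples).
- Gower treats all traits within a dimension equally; no trait weighting.
- Missing trait values are rejected, not imputed.
- Species matching is exact after whitespace/underscore unification; no
  fuzzy name resolution against taxonomies.
- The PSV permutation test conditions on group sizes; it does not model
  the classification process that produced them.
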