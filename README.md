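# phyloniche

Constraints and phylogenetic structure of functional niche space, built for
the kind of question lizard evolutionary ecology keeps asking: do species
fill trait space freely, or do ecological filters and shared ancestry
restrict them to a limited set of viable trait combinations?

The package implements a complete, tested analysis pipeline:

1. **Niche-space reduction.** A species × trait table with mixed types
   (binary flags, counts, proportions, measurements) is split into six
   niche dimensions — habitat, trophic, life history, metabolic, defense,
   ecomorphology. Each dimension's block is converted to an unweighted
   Gower dissimilarity; the first principal-coordinates (classical scaling)
   axis is that dimension's *functional variable*. A standardized PCA of
   the six variables ordinates species in niche space, and Gaussian KDE
   delineates the regions holding 50/95/99% of species.
2. **Hypervolume null models.** The occupied volume is the 6-D convex hull
   of the species coordinates, V = vol(conv{x₁,…,xₙ}), compared against
   four null models of species distribution: NM1 independent uniform per
   axis, NM2 independent normal, NM3 independently permuted observed
   marginals, NM4 multivariate normal with the observed covariance. The
   one-tailed p-value is (1 + #{V_null ≤ V_obs})/(1 + R) and the percent
   reduction is 100·(V̄_null − V_obs)/V̄_null.
3. **Functional groups.** Species are classified into the fixed 24-label
   space {SW, WF} × {AQ, F, C, T, S, A} × {D, N} (foraging × habitat ×
   activity); mixed strategies (cathemeral, mixed foraging, habitat
   generalists) produce multi-group membership via the Cartesian product
   of a species' attribute sets.
4. **Phylogenetic structure.** Per-group phylogenetic species variability,
   PSV = (n·tr(C) − ΣC)/(n(n−1)) on the group's phylogenetic correlation
   submatrix (1 = star-like unrelatedness, 0 = maximal relatedness), with
   a permutation test against random same-sized draws from the pool; and
   phylogenetic fuzzy weighting of group composition (matrix P), followed
   by PCoA of square-rooted Bray–Curtis dissimilarities — the PCPS axes,
   retained when they explain > 10% of variance.
5. **Synthetic data.** Pure-birth trees with forced basal clades,
   Brownian-motion traits with a conservatism dial in [0, 1], conserved
   multi-state ecological attributes, and direct functional-variable
   generators with known correlation — so every stage is testable without
   any external dataset.

## Worked example

The numbered drivers under `analysis/` run the whole study on a simulated
96-species system (two deep clades, conservatism 0.7):

```
python analysis/01_simulate.py
python analysis/02_reduce_niche_space.py
python analysis/03_hypervolume_nulls.py
python analysis/04_functional_groups.py
python analysis/05_phylogenetic_structure.py
```

which prints (abridged):

```
PCA: first three axes model 74.6% of variance (43.2%, 17.2%, 14.3%)
observed 6-D hull volume: 0.002852
  NM1: null mean 0.007364, reduction 61.3%, p = 0.002 (smaller than null)
  NM2: null mean 0.00696,  reduction 59.0%, p = 0.002 (smaller than null)
  NM3: null mean 0.00555,  reduction 48.6%, p = 0.002 (smaller than null)
  NM4: null mean 0.00357,  reduction 20.1%, p = 0.128 (not distinguishable)
96 species occupy 20/24 functional groups
species in more than one group: 46 (48%)
family richness vs. group count: r = 0.71 (p = 9.9e-05)
mean PSV observed = 0.5315; null = 0.7575 [0.6843, 0.8151] -> clustered
PCPS variance: 61.7%, 12.5%, 5.4%, 4.7%; retained axes (>10%): [1, 2]
```

Read: the realized niche hypervolume is significantly smaller than the
uncorrelated nulls (NM1–NM3) and closest to the correlation-preserving
NM4 — trait combinations are constrained, largely through inter-variable
correlation; functional groups are phylogenetically clustered (observed
mean PSV below the null's 2.5% quantile); and the leading PCPS axis,
carrying most of the compositional variance, tracks the basal split
between the two simulated clades.

A `phyloniche` CLI exposes the same stages (`simulate`, `validate`,
`reduce`, `hypervolume`, `classify-groups`, `psv`, `pcps-cmd`, `run-all`);
`run-all` drives everything from a YAML config.

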