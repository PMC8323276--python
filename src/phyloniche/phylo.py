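"""Phylogenetic structure of functional-group composition.

Two complementary analyses:

* **PSV** (phylogenetic species variability) per functional group, with a
  permutation test drawing same-sized random species sets from the pool —
  an observed mean below the null's 2.5% quantile indicates phylogenetic
  clustering, above the 97.5% quantile overdispersion.
* **Phylogenetic fuzzy weighting** of group composition (matrix P), followed
  by square-rooted Bray–Curtis dissimilarities and principal coordinates —
  the PCPS axes, whose leading axis reflects the deepest splits in the tree.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import dendropy
import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from phyloniche.errors import InvalidParameterError, ValidationError
from phyloniche.groups import GroupAssignment
from phyloniche.reduction import DistanceMatrix, OrdinationResult, pcoa

__all__ = [
    "PhyloCorrelation",
    "PSVReport",
    "MatrixP",
    "PCPSResult",
    "cophenetic_matrix",
    "phylo_correlation",
    "psv",
    "psv_permutation_test",
    "fuzzy_weighting",
    "pcps",
]


# ---------------------------------------------------------------------------
# Tree distances
# ---------------------------------------------------------------------------


def cophenetic_matrix(
    tree: dendropy.Tree,
) -> tuple[list[str], np.ndarray, np.ndarray]:
    """Tip labels, patristic distance matrix, and root-to-tip depths.

    Computed in a single vectorized postorder pass:
    ``d(i, j) = depth_i + depth_j - 2 * depth_MRCA(i, j)``, which holds for
    any rooted tree with branch lengths, ultrametric or not.
    """
    leaves = list(tree.leaf_node_iter())
    ids = [leaf.taxon.label for leaf in leaves]
    index = {id(leaf): i for i, leaf in enumerate(leaves)}
    n = len(leaves)

    depth: dict[int, float] = {id(tree.seed_node): float(tree.seed_node.edge.length or 0.0)}
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        depth[id(node)] = depth[id(node.parent_node)] + float(node.edge.length or 0.0)

    depths = np.array([depth[id(leaf)] for leaf in leaves])
    D = np.zeros((n, n))
    tips_below: dict[int, np.ndarray] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            tips_below[id(node)] = np.array([index[id(node)]])
            continue
        child_sets = [tips_below.pop(id(c)) for c in node.child_nodes()]
        node_depth = depth[id(node)]
        for a in range(len(child_sets)):
            for b in range(a + 1, len(child_sets)):
                ia, ib = child_sets[a], child_sets[b]
                block = depths[ia][:, None] + depths[ib][None, :] - 2.0 * node_depth
                D[np.ix_(ia, ib)] = block
                D[np.ix_(ib, ia)] = block.T
        tips_below[id(node)] = np.concatenate(child_sets)
    return ids, D, depths


@dataclass
class PhyloCorrelation:
    """Species x species phylogenetic correlation.

    ``C[i, j]`` is the shared root-to-MRCA branch length divided by the
    geometric mean of the two root-to-tip depths; the diagonal is exactly 1.
    For an ultrametric tree of depth T this reduces to shared depth / T.
    """

    matrix: np.ndarray
    ids: list[str]

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape[0] != m.shape[1] or m.shape[0] != len(self.ids):
            raise ValidationError("correlation matrix shape does not match ids")
        self.matrix = m
        self._pos = {s: i for i, s in enumerate(self.ids)}

    def submatrix(self, members: Sequence[str]) -> np.ndarray:
        try:
            idx = [self._pos[s] for s in members]
        except KeyError as exc:
            raise ValidationError(f"species {exc.args[0]!r} not in correlation matrix")
        return self.matrix[np.ix_(idx, idx)]


def phylo_correlation(tree: dendropy.Tree) -> PhyloCorrelation:
    """Phylogenetic correlation matrix of a tree's tips."""
    ids, D, depths = cophenetic_matrix(tree)
    if (depths <= 0).any():
        bad = ids[int(np.argmin(depths))]
        raise ValidationError(f"tip {bad!r} has zero root-to-tip depth")
    shared = (depths[:, None] + depths[None, :] - D) / 2.0
    C = shared / np.sqrt(depths[:, None] * depths[None, :])
    np.fill_diagonal(C, 1.0)
    return PhyloCorrelation(C, ids)


# ---------------------------------------------------------------------------
# PSV
# ---------------------------------------------------------------------------


def psv(C: PhyloCorrelation | np.ndarray, members: Sequence[str] | None = None) -> float:
    """Phylogenetic species variability of a species set.

    ``PSV = (n * trace(C_m) - sum(C_m)) / (n * (n - 1))`` on the member
    submatrix; 1 means maximally unrelated tips (star phylogeny), 0 maximal
    relatedness (all pairwise correlations 1). Branch-length units never
    enter because C is a correlation matrix.
    """
    if isinstance(C, PhyloCorrelation):
        Cm = C.submatrix(list(members)) if members is not None else C.matrix
    else:
        Cm = np.asarray(C, dtype=float)
    n = Cm.shape[0]
    if n < 2:
        raise InvalidParameterError("PSV needs at least 2 species")
    return float((n * np.trace(Cm) - Cm.sum()) / (n * (n - 1)))


@dataclass
class PSVReport:
    """Observed mean PSV against the random-draw null distribution."""

    per_group: dict[str, float]
    observed_mean: float
    null_mean: float
    lower: float
    upper: float
    R: int
    alpha: float
    verdict: str
    excluded_groups: list[str]
    null_values: np.ndarray

    def to_dict(self) -> dict:
        return {
            "per_group_psv": {k: float(v) for k, v in self.per_group.items()},
            "observed_mean_psv": self.observed_mean,
            "null_mean_psv": self.null_mean,
            "lower_limit": self.lower,
            "upper_limit": self.upper,
            "R": self.R,
            "alpha": self.alpha,
            "verdict": self.verdict,
            "excluded_groups": self.excluded_groups,
        }


def psv_permutation_test(
    ga: GroupAssignment,
    C: PhyloCorrelation,
    R: int = 1000,
    alpha: float = 0.05,
    seed: int | None = None,
) -> PSVReport:
    """Permutation test of phylogenetic structure in group composition.

    The observed statistic is the mean PSV over groups with at least two
    members (singletons are excluded with a warning). Each of the R null
    replicates redraws, for every group independently, a uniform random
    species subset of the same size from the pool (without replacement
    within a group), and recomputes the mean. The empirical alpha/2 and
    1 - alpha/2 quantiles of the null bound the verdict: ``clustered`` below
    the lower limit, ``overdispersed`` above the upper, else ``random``.
    """
    if R < 100:
        warnings.warn("R < 100 makes the null quantiles unstable", stacklevel=2)
    pool = [s for s in ga.species_ids if s in C._pos]
    if len(pool) < 2:
        raise InvalidParameterError("species pool on the tree is too small")
    pool_idx = np.array([C._pos[s] for s in pool])

    sizes: list[int] = []
    per_group: dict[str, float] = {}
    excluded: list[str] = []
    for label in ga.labels:
        members = [s for s in ga.members(label) if s in C._pos]
        if len(members) == 0:
            continue
        if len(members) < 2:
            excluded.append(label)
            continue
        per_group[label] = psv(C, members)
        sizes.append(len(members))
    if excluded:
        warnings.warn(
            f"groups excluded from PSV (fewer than 2 members): {excluded}",
            stacklevel=2,
        )
    if not per_group:
        raise InvalidParameterError("no group has at least 2 members on the tree")

    observed = float(np.mean(list(per_group.values())))
    rng = np.random.default_rng(seed)
    M = C.matrix
    null = np.empty(R)
    for r in range(R):
        vals = np.empty(len(sizes))
        for g, m in enumerate(sizes):
            sub = rng.choice(pool_idx, size=m, replace=False)
            Cm = M[np.ix_(sub, sub)]
            vals[g] = (m * np.trace(Cm) - Cm.sum()) / (m * (m - 1))
        null[r] = vals.mean()
    lower, upper = np.quantile(null, [alpha / 2.0, 1.0 - alpha / 2.0])
    if observed < lower:
        verdict = "clustered"
    elif observed > upper:
        verdict = "overdispersed"
    else:
        verdict = "random"
    return PSVReport(
        per_group, observed, float(null.mean()), float(lower), float(upper),
        R, alpha, verdict, excluded, null,
    )


# ---------------------------------------------------------------------------
# Phylogenetic fuzzy weighting and PCPS
# ---------------------------------------------------------------------------


@dataclass
class MatrixP:
    """Group x species phylogenetically weighted composition; rows sum to 1."""

    values: pd.DataFrame

    def __post_init__(self) -> None:
        v = self.values.to_numpy(dtype=float)
        if (v < -1e-12).any():
            raise ValidationError("matrix P entries must be non-negative")
        sums = v.sum(axis=1)
        if not np.allclose(sums, 1.0, atol=1e-9):
            raise ValidationError("matrix P rows must sum to 1")


def fuzzy_weighting(
    tree: dendropy.Tree,
    ga: GroupAssignment,
    similarity: str = "cophenetic",
) -> MatrixP:
    """Phylogenetic fuzzy weighting of group composition (matrix P).

    Pairwise phylogenetic similarity ``S = 1 - d / max(d)`` (cophenetic
    distance, unit self-similarity) is standardized per species so each
    species distributes one unit of belonging across its phylogenetic
    neighborhood (matrix Q); composing the row-standardized group incidence
    with Q yields the group x species matrix P, whose rows sum to 1.
    ``similarity="shared-branch"`` substitutes the shared-branch correlation
    matrix for S.
    """
    if similarity not in ("cophenetic", "shared-branch"):
        raise InvalidParameterError(f"unknown similarity {similarity!r}")
    ids, D, _ = cophenetic_matrix(tree)
    on_tree = set(ids)
    missing = [s for s in ga.species_ids if s not in on_tree]
    if missing:
        warnings.warn(
            f"{len(missing)} species absent from the tree dropped before "
            f"matrix P construction: {missing[:5]}{'...' if len(missing) > 5 else ''}",
            stacklevel=2,
        )
    species = [s for s in ga.species_ids if s in on_tree]
    if len(species) < 2:
        raise InvalidParameterError("need at least 2 species on the tree")
    pos = {s: i for i, s in enumerate(ids)}
    idx = np.array([pos[s] for s in species])

    if similarity == "cophenetic":
        Dsub = D[np.ix_(idx, idx)]
        dmax = Dsub.max()
        if dmax <= 0:
            raise InvalidParameterError(
                "maximum cophenetic distance is zero; similarities undefined"
            )
        S = 1.0 - Dsub / dmax
    else:
        S = phylo_correlation(tree).matrix[np.ix_(idx, idx)]
    Q = S / S.sum(axis=1, keepdims=True)

    W = ga.membership.loc[species].T.to_numpy(dtype=float)  # groups x species
    group_labels = list(ga.membership.columns)
    nonempty = W.sum(axis=1) > 0
    if not nonempty.all():
        W = W[nonempty]
        group_labels = [l for l, keep in zip(group_labels, nonempty) if keep]
    W = W / W.sum(axis=1, keepdims=True)
    P = W @ Q
    frame = pd.DataFrame(P, index=pd.Index(group_labels, name="group"), columns=species)
    return MatrixP(frame)


@dataclass
class PCPSResult:
    """Group coordinates on phylogenetic-structure axes.

    Axes whose variance share exceeds the retention threshold (10% by
    default) are flagged ``retained``; ``species_correlations`` gives the
    Pearson correlation of each species' column of P with each retained axis
    across groups, for clade interpretation.
    """

    ordination: OrdinationResult
    retained: list[bool]
    species_correlations: pd.DataFrame

    @property
    def scores(self) -> pd.DataFrame:
        return self.ordination.scores

    @property
    def pct_variance(self) -> np.ndarray:
        return self.ordination.pct_variance

    def to_dict(self) -> dict:
        return {
            "pct_variance": [float(v) for v in self.pct_variance],
            "retained": list(self.retained),
        }


def sqrt_bray_curtis(P: MatrixP) -> DistanceMatrix:
    """Square-rooted Bray–Curtis dissimilarities between the rows of P."""
    X = P.values.to_numpy(dtype=float)
    d = squareform(np.sqrt(pdist(X, metric="braycurtis")))
    return DistanceMatrix(d, list(P.values.index))


def pcps(P: MatrixP, retain_threshold: float = 10.0) -> PCPSResult:
    """Principal coordinates of phylogenetic structure.

    PCoA of the square-rooted Bray–Curtis dissimilarities between the rows
    of matrix P; the leading axis captures the deepest phylogenetic splits
    among the groups' compositions. Axes explaining more than
    ``retain_threshold`` percent of the (positive) variance are retained.
    """
    if P.values.shape[0] < 3:
        raise InvalidParameterError("PCPS needs at least 3 groups")
    d = sqrt_bray_curtis(P)
    if not d.matrix.any():
        raise ValidationError(
            "all groups have identical phylogenetically weighted composition"
        )
    ordn = pcoa(d)
    retained = [bool(v > retain_threshold) for v in ordn.pct_variance]

    scores = ordn.scores.to_numpy()
    Pv = P.values.to_numpy(dtype=float)
    n_axes = scores.shape[1]
    corr = np.full((Pv.shape[1], n_axes), np.nan)
    for j in range(n_axes):
        sj = scores[:, j]
        s_c = sj - sj.mean()
        denom_s = np.sqrt((s_c**2).sum())
        cols = Pv - Pv.mean(axis=0)
        denom_p = np.sqrt((cols**2).sum(axis=0))
        ok = (denom_p > 0) & (denom_s > 0)
        corr[ok, j] = (cols[:, ok].T @ s_c) / (denom_p[ok] * denom_s)
    corr_df = pd.DataFrame(
        corr, index=P.values.columns, columns=list(ordn.scores.columns)
    )
    return PCPSResult(ordn, retained, corr_df)
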