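"""Reduction of mixed-type trait blocks to functional variables.

Each niche dimension's trait block is converted to an unweighted Gower
dissimilarity and summarized by the first principal-coordinates (classical
scaling) axis; the six resulting functional variables are ordinated by PCA
on standardized columns, and kernel density estimation delineates
highest-density occupancy regions in the reduced space.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from phyloniche.errors import InvalidParameterError, ValidationError
from phyloniche.io import DIMENSIONS, TraitTable

__all__ = [
    "DistanceMatrix",
    "OrdinationResult",
    "NicheReduction",
    "KDERegions",
    "gower_distance",
    "pcoa",
    "build_functional_variables",
    "pca_functional",
    "kde_regions",
]


@dataclass
class DistanceMatrix:
    """Square symmetric dissimilarity matrix with a species order."""

    matrix: np.ndarray
    ids: list[str]

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValidationError(f"distance matrix must be square, got {m.shape}")
        if m.shape[0] != len(self.ids):
            raise ValidationError("distance matrix size does not match id count")
        if not np.allclose(m, m.T, atol=1e-12):
            raise ValidationError("distance matrix must be symmetric")
        if np.abs(np.diag(m)).max(initial=0.0) > 1e-12:
            raise ValidationError("distance matrix must have a zero diagonal")
        if (m < -1e-12).any():
            raise ValidationError("distances must be non-negative")
        m = np.clip((m + m.T) / 2.0, 0.0, None)
        np.fill_diagonal(m, 0.0)
        self.matrix = m

    @property
    def n(self) -> int:
        return len(self.ids)


@dataclass
class OrdinationResult:
    """Scores, eigenvalues and variance shares of an ordination.

    ``pct_variance`` is computed over the positive eigenvalues only (Gower
    dissimilarities are generally non-Euclidean, so classical scaling can
    produce negative eigenvalues; no Cailliez/Lingoes correction is applied
    by default). For PCA, ``contributions`` holds the percentage each input
    variable contributes to each axis (columns sum to 100) and
    ``variable_correlations`` / ``correlation_pvalues`` the Pearson
    correlation of each variable with each axis score; variables
    contributing < 5% to an axis are flagged not-tested (NaN).
    """

    scores: pd.DataFrame
    eigenvalues: np.ndarray
    pct_variance: np.ndarray
    contributions: pd.DataFrame | None = None
    variable_correlations: pd.DataFrame | None = None
    correlation_pvalues: pd.DataFrame | None = None

    @property
    def n_axes(self) -> int:
        return self.scores.shape[1]

    def to_dict(self) -> dict:
        out = {
            "eigenvalues": [float(v) for v in self.eigenvalues],
            "pct_variance": [float(v) for v in self.pct_variance],
        }
        if self.contributions is not None:
            out["contributions"] = self.contributions.round(10).to_dict()
        if self.variable_correlations is not None:
            out["variable_correlations"] = {
                col: {
                    k: (None if pd.isna(v) else float(v))
                    for k, v in self.variable_correlations[col].items()
                }
                for col in self.variable_correlations.columns
            }
            out["correlation_pvalues"] = {
                col: {
                    k: (None if pd.isna(v) else float(v))
                    for k, v in self.correlation_pvalues[col].items()
                }
                for col in self.correlation_pvalues.columns
            }
        return out


# ---------------------------------------------------------------------------
# Gower distance
# ---------------------------------------------------------------------------


def gower_distance(
    traits: TraitTable,
    dimension: str,
    binary_mode: str = "symmetric",
) -> DistanceMatrix:
    """Unweighted Gower dissimilarity over one niche dimension's traits.

    Per-trait contributions are the range-normalized absolute difference for
    quantitative traits and the simple (symmetric) mismatch for binary
    traits; the dissimilarity is their unweighted mean. With
    ``binary_mode="asymmetric"`` a binary trait is excluded from a pair's
    mean when both species score 0 (Jaccard-style treatment of rare states).

    Quantitative traits with zero range carry no information and are dropped
    with a warning.
    """
    if binary_mode not in ("symmetric", "asymmetric"):
        raise InvalidParameterError(f"unknown binary_mode {binary_mode!r}")
    cols = traits.traits_for(dimension)
    if not cols:
        raise InvalidParameterError(f"dimension {dimension!r} has no traits")
    ids = traits.species_ids
    n = len(ids)
    if n < 2:
        raise InvalidParameterError("Gower distance needs at least 2 species")

    num = np.zeros((n, n))
    den = np.zeros((n, n))
    for trait in cols:
        x = traits.data[trait].to_numpy(dtype=float)
        if traits.meta.loc[trait, "type"] == "quantitative":
            rng = x.max() - x.min()
            if rng <= 0:
                warnings.warn(
                    f"trait {trait!r} has zero range in dimension {dimension!r}; "
                    "dropped from the Gower mean",
                    stacklevel=2,
                )
                continue
            num += np.abs(x[:, None] - x[None, :]) / rng
            den += 1.0
        else:
            mismatch = (x[:, None] != x[None, :]).astype(float)
            if binary_mode == "asymmetric":
                both_zero = (x[:, None] == 0) & (x[None, :] == 0)
                valid = ~both_zero
                num += mismatch * valid
                den += valid
            else:
                num += mismatch
                den += 1.0

    with np.errstate(invalid="ignore", divide="ignore"):
        d = np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.0)
    d = np.clip(d, 0.0, 1.0)
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(d, list(ids))


# ---------------------------------------------------------------------------
# Principal coordinates (classical scaling)
# ---------------------------------------------------------------------------


def _fix_axis_signs(scores: np.ndarray, ids: Sequence[str]) -> np.ndarray:
    """Resolve eigenvector sign indeterminacy.

    Each axis is flipped, if necessary, so the score of the alphabetically
    first species with a non-zero score on that axis is non-negative.
    """
    order = np.argsort(np.asarray(ids, dtype=object))
    for j in range(scores.shape[1]):
        col = scores[:, j]
        for i in order:
            if abs(col[i]) > 1e-12:
                if col[i] < 0:
                    scores[:, j] = -col
                break
    return scores


def pcoa(d: DistanceMatrix, n_axes: int | None = None) -> OrdinationResult:
    """Classical (metric) scaling of a dissimilarity matrix.

    Double-centers -d^2/2, eigendecomposes, orders axes by descending
    eigenvalue and scales eigenvectors by the square root of their
    eigenvalue. Variance percentages are taken over the positive eigenvalues
    only. Axis signs follow the alphabetical-species convention of
    :func:`_fix_axis_signs`.
    """
    D = d.matrix
    n = d.n
    if not D.any():
        warnings.warn("all distances are zero; returning a single zero axis",
                      stacklevel=2)
        scores = pd.DataFrame(
            np.zeros((n, 1)), index=list(d.ids), columns=["axis1"]
        )
        return OrdinationResult(scores, np.zeros(1), np.zeros(1))

    B = D**2
    B = -0.5 * B
    row_mean = B.mean(axis=1, keepdims=True)
    col_mean = B.mean(axis=0, keepdims=True)
    B = B - row_mean - col_mean + B.mean()
    eigval, eigvec = np.linalg.eigh((B + B.T) / 2.0)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]

    tol = max(abs(eigval[0]), abs(eigval[-1])) * 1e-10
    pos = eigval > tol
    lam = eigval[pos]
    vec = eigvec[:, pos]
    scores = vec * np.sqrt(lam)[None, :]
    scores = _fix_axis_signs(scores, d.ids)
    pct = 100.0 * lam / lam.sum()

    k = scores.shape[1] if n_axes is None else min(n_axes, scores.shape[1])
    frame = pd.DataFrame(
        scores[:, :k],
        index=list(d.ids),
        columns=[f"axis{i + 1}" for i in range(k)],
    )
    frame.index.name = "species"
    return OrdinationResult(frame, eigval, pct[:k])


# ---------------------------------------------------------------------------
# Functional variables (one per niche dimension)
# ---------------------------------------------------------------------------


@dataclass
class NicheReduction:
    """Six functional variables and their per-dimension ordinations.

    ``variables`` holds the first-PCoA-axis score of every species on each
    niche dimension; ``dimension_variance`` the percentage of (positive)
    variance each dimension's leading axes capture.
    """

    variables: pd.DataFrame
    dimension_variance: pd.DataFrame
    ordinations: dict[str, OrdinationResult] = field(default_factory=dict)

    @property
    def axis1_pct_variance(self) -> dict[str, float]:
        return {d: float(self.dimension_variance.loc[d, "axis1_pct"])
                for d in self.dimension_variance.index}


def build_functional_variables(
    traits: TraitTable,
    dimensions: Sequence[str] | None = None,
    binary_mode: str = "symmetric",
) -> NicheReduction:
    """First-PCoA-axis score per niche dimension for every species.

    Requires every requested dimension (default: all six) to carry at least
    one trait; the per-dimension variance table is the tabular analogue of
    reporting how much interspecific variation each functional variable
    captures.
    """
    dims = tuple(dimensions) if dimensions is not None else DIMENSIONS
    missing = [d for d in dims if not traits.traits_for(d)]
    if missing:
        raise InvalidParameterError(
            f"dimension(s) without traits: {missing}"
        )
    cols = {}
    var_rows = []
    ordinations = {}
    for dim in dims:
        dm = gower_distance(traits, dim, binary_mode=binary_mode)
        ord_res = pcoa(dm)
        ordinations[dim] = ord_res
        cols[dim] = ord_res.scores["axis1"]
        pct = ord_res.pct_variance
        var_rows.append(
            {
                "dimension": dim,
                "axis1_pct": float(pct[0]) if len(pct) > 0 else 0.0,
                "axis2_pct": float(pct[1]) if len(pct) > 1 else 0.0,
                "axis3_pct": float(pct[2]) if len(pct) > 2 else 0.0,
            }
        )
    variables = pd.DataFrame(cols, index=traits.species_ids)
    variables.index.name = "species"
    dim_var = pd.DataFrame(var_rows).set_index("dimension")
    return NicheReduction(variables, dim_var, ordinations)


# ---------------------------------------------------------------------------
# PCA of the functional variables
# ---------------------------------------------------------------------------


def pca_functional(
    fv: pd.DataFrame,
    standardize: bool = True,
    contribution_floor: float = 5.0,
) -> OrdinationResult:
    """PCA ordination of species in functional niche space.

    Columns are standardized to zero mean and unit variance by default (the
    six functional variables are ordination scores on unrelated scales).
    Per-axis variable contributions are ``100 * loading^2`` (unit-norm
    eigenvectors, so each axis sums to 100). Correlations between variables
    and axis scores carry two-sided p-values; variables contributing less
    than ``contribution_floor`` percent to an axis are not tested (NaN).
    """
    X = fv.to_numpy(dtype=float)
    n, p = X.shape
    if n <= p:
        raise InvalidParameterError(
            f"PCA needs more species than variables (got {n} x {p})"
        )
    sd = X.std(axis=0, ddof=1)
    constant = [fv.columns[j] for j in range(p) if sd[j] == 0]
    if constant:
        raise ValidationError(f"constant column(s): {constant}")
    Xc = X - X.mean(axis=0)
    if standardize:
        Xc = Xc / sd

    # SVD-based PCA; eigenvalues are sample variances of the scores
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    eigval = s**2 / (n - 1)
    scores = U * s
    scores = _fix_axis_signs(scores, list(fv.index))
    # re-derive the (possibly flipped) loadings from the sign-fixed scores
    loadings = np.zeros_like(Vt)
    for j in range(p):
        denom = s[j] if s[j] > 0 else 1.0
        loadings[j] = (Xc.T @ scores[:, j]) / (denom**2)

    axes = [f"axis{i + 1}" for i in range(p)]
    score_df = pd.DataFrame(scores, index=fv.index, columns=axes)
    score_df.index.name = "species"
    pct = 100.0 * eigval / eigval.sum()
    contrib = pd.DataFrame(
        100.0 * loadings.T**2 / (loadings**2).sum(axis=1)[None, :],
        index=fv.columns,
        columns=axes,
    )

    corr = pd.DataFrame(np.nan, index=fv.columns, columns=axes)
    pval = pd.DataFrame(np.nan, index=fv.columns, columns=axes)
    for j, axis in enumerate(axes):
        if eigval[j] <= 1e-12:
            continue
        for var in fv.columns:
            if contrib.loc[var, axis] < contribution_floor:
                continue  # not-tested convention for minor contributors
            r, p_two = stats.pearsonr(fv[var].to_numpy(dtype=float), scores[:, j])
            corr.loc[var, axis] = r
            pval.loc[var, axis] = p_two

    return OrdinationResult(score_df, eigval, pct, contrib, corr, pval)


# ---------------------------------------------------------------------------
# KDE occupancy regions
# ---------------------------------------------------------------------------


@dataclass
class KDERegions:
    """Highest-density occupancy regions of the reduced niche space."""

    grid_axes: list[np.ndarray]
    density: np.ndarray
    thresholds: dict[float, float]
    masks: dict[float, np.ndarray]
    membership: pd.DataFrame
    fraction_inside: dict[float, float]
    grid_size: int
    bandwidth_factor: float

    def summary(self) -> dict:
        return {
            "levels": sorted(self.thresholds),
            "thresholds": {str(k): float(v) for k, v in self.thresholds.items()},
            "fraction_inside": {
                str(k): float(v) for k, v in self.fraction_inside.items()
            },
            "grid_size": self.grid_size,
            "bandwidth_factor": float(self.bandwidth_factor),
        }


def kde_regions(
    scores: pd.DataFrame | np.ndarray,
    levels: Sequence[float] = (50.0, 95.0, 99.0),
    grid_size: int | None = None,
    bw_method: str | float = "silverman",
) -> KDERegions:
    """Gaussian-kernel density regions containing given percentages of species.

    For each level L the region is the smallest grid superlevel set whose
    density threshold keeps at least L% of the sample points inside, so
    regions are nested by construction. The default bandwidth is the
    normal-reference (Silverman) rule; grid resolution defaults to 64 per
    axis in 2-D and 32 in 3-D.
    """
    if isinstance(scores, pd.DataFrame):
        ids = list(scores.index)
        X = scores.to_numpy(dtype=float)
    else:
        X = np.asarray(scores, dtype=float)
        ids = [f"p{i}" for i in range(X.shape[0])]
    n, k = X.shape
    if k not in (2, 3):
        raise InvalidParameterError(f"KDE regions support 2-D or 3-D scores, got {k}-D")
    if n < 2:
        raise InvalidParameterError("KDE needs at least 2 species")
    levels = sorted(float(l) for l in levels)
    if any(not (0.0 < l < 100.0) for l in levels):
        raise InvalidParameterError("levels must lie strictly between 0 and 100")
    if grid_size is None:
        grid_size = 64 if k == 2 else 32

    kde = stats.gaussian_kde(X.T, bw_method=bw_method)
    pad = 3.0 * kde.factor * X.std(axis=0, ddof=1)
    axes = [
        np.linspace(X[:, j].min() - pad[j], X[:, j].max() + pad[j], grid_size)
        for j in range(k)
    ]
    mesh = np.meshgrid(*axes, indexing="ij")
    grid_points = np.vstack([m.ravel() for m in mesh])
    density = kde(grid_points).reshape([grid_size] * k)
    sample_density = kde(X.T)

    sorted_dens = np.sort(sample_density)[::-1]
    thresholds, masks, fractions = {}, {}, {}
    for L in levels:
        m = int(np.ceil(L / 100.0 * n))
        t = sorted_dens[m - 1]
        thresholds[L] = float(t)
        masks[L] = density >= t
        fractions[L] = float((sample_density >= t).mean())

    membership = pd.DataFrame(
        {f"in_{L:g}": sample_density >= thresholds[L] for L in levels},
        index=pd.Index(ids, name="species"),
    )
    return KDERegions(
        axes, density, thresholds, masks, membership, fractions,
        grid_size, float(kde.factor),
    )
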