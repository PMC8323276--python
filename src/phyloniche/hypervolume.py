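"""Convex-hull functional hypervolume and null-model constraint tests.

The occupied niche hypervolume is the volume of the convex hull of species
coordinates in the 6-D functional space. Four null models generate
alternative species distributions in that space:

NM1  independent uniform per axis over the observed range,
NM2  independent normal per axis (observed mean and sd),
NM3  observed marginals with each axis independently permuted
     (correlations destroyed, marginals preserved exactly),
NM4  multivariate normal with the observed mean vector and covariance.

The test is one-tailed for a *smaller* observed volume; the p-value uses
the add-one permutation convention (1 + b) / (1 + R).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull, QhullError

from phyloniche.errors import DegenerateGeometryError, InvalidParameterError

NULL_MODELS = ("NM1", "NM2", "NM3", "NM4")


def _as_matrix(fv) -> np.ndarray:
    X = fv.to_numpy(dtype=float) if isinstance(fv, pd.DataFrame) else np.asarray(fv, dtype=float)
    if X.ndim != 2:
        raise InvalidParameterError("functional variables must be a 2-D array")
    return X


def convex_hull_volume(points) -> float:
    """d-dimensional content of the convex hull of an n x d point cloud.

    Raises :class:`DegenerateGeometryError` for n <= d or affinely
    rank-deficient input; points are never jittered, since silent
    perturbation would corrupt null distributions built from these volumes.
    """
    X = _as_matrix(points)
    n, d = X.shape
    if n <= d:
        raise DegenerateGeometryError(
            f"need more than {d} points for a {d}-D hull, got {n}"
        )
    if np.linalg.matrix_rank(X - X.mean(axis=0)) < d:
        raise DegenerateGeometryError("points are affinely rank-deficient")
    try:
        return float(ConvexHull(X).volume)
    except QhullError as exc:  # pragma: no cover - rank check catches most
        raise DegenerateGeometryError(str(exc)) from exc


def null_sample(
    fv,
    model: str,
    rng: np.random.Generator | int | None = None,
) -> np.ndarray:
    """One replicate of species coordinates under a null model (see module doc)."""
    X = _as_matrix(fv)
    if model not in NULL_MODELS:
        raise InvalidParameterError(
            f"unknown null model {model!r}; expected one of {NULL_MODELS}"
        )
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    n, d = X.shape
    if model == "NM1":
        lo, hi = X.min(axis=0), X.max(axis=0)
        return rng.uniform(lo, hi, size=(n, d))
    if model == "NM2":
        mu, sd = X.mean(axis=0), X.std(axis=0, ddof=1)
        return mu + sd * rng.standard_normal((n, d))
    if model == "NM3":
        out = X.copy()
        for j in range(d):
            out[:, j] = rng.permutation(out[:, j])
        return out
    # NM4
    mu = X.mean(axis=0)
    cov = np.cov(X, rowvar=False, ddof=1)
    L = _safe_cholesky(cov)
    return mu + rng.standard_normal((n, d)) @ L.T


def _safe_cholesky(cov: np.ndarray) -> np.ndarray:
    try:
        return np.linalg.cholesky(cov)
    except np.linalg.LinAlgError:
        warnings.warn(
            "observed covariance is not positive definite; "
            "repaired by clipping eigenvalues",
            stacklevel=2,
        )
        w, v = np.linalg.eigh((cov + cov.T) / 2.0)
        w = np.clip(w, 1e-12 * max(w.max(), 1.0), None)
        return np.linalg.cholesky(v @ np.diag(w) @ v.T)


@dataclass
class ModelResult:
    null_volumes: np.ndarray
    null_mean: float
    ratio: float
    p_value: float


@dataclass
class HypervolumeReport:
    """Observed hull volume against per-model null volume distributions.

    ``ratio`` is the percent reduction of the observed volume relative to
    the null mean, ``100 * (null_mean - observed) / null_mean``; the
    per-replicate-mean alternative is available via
    ``hypervolume_test(ratio_mode="per_replicate")``.
    """

    observed_volume: float
    models: dict[str, ModelResult]
    R: int
    seed: int | None

    def to_dict(self) -> dict:
        return {
            "observed_volume": self.observed_volume,
            "R": self.R,
            "seed": self.seed,
            "models": {
                name: {
                    "null_mean": res.null_mean,
                    "ratio": res.ratio,
                    "p_value": res.p_value,
                    "null_volumes": [float(v) for v in res.null_volumes],
                }
                for name, res in self.models.items()
            },
        }


def reduction_ratio(null_mean: float, observed: float) -> float:
    """Percent reduction of the observed volume relative to a null mean."""
    if null_mean <= 0:
        return float("nan")
    return 100.0 * (null_mean - observed) / null_mean


def hypervolume_test(
    fv,
    models: Sequence[str] = NULL_MODELS,
    R: int = 999,
    seed: int | None = None,
    ratio_mode: str = "null_mean",
) -> HypervolumeReport:
    """Test whether the occupied hypervolume is smaller than expected.

    For each requested null model, R replicate point clouds are drawn and
    their hull volumes collected; the one-tailed p-value is
    ``(1 + #{null <= observed}) / (R + 1)``. Each model consumes an
    independent random substream of ``seed``, so adding or dropping models
    does not shift the others' replicates.
    """
    if R < 1:
        raise InvalidParameterError("R must be >= 1")
    if ratio_mode not in ("null_mean", "per_replicate"):
        raise InvalidParameterError(f"unknown ratio_mode {ratio_mode!r}")
    X = _as_matrix(fv)
    observed = convex_hull_volume(X)

    results: dict[str, ModelResult] = {}
    for model in models:
        if model not in NULL_MODELS:
            raise InvalidParameterError(f"unknown null model {model!r}")
        stream = np.random.default_rng(
            np.random.SeedSequence(entropy=seed, spawn_key=(NULL_MODELS.index(model),))
        )
        volumes = np.empty(R)
        for r in range(R):
            try:
                volumes[r] = convex_hull_volume(null_sample(X, model, stream))
            except DegenerateGeometryError:
                # one resample, then give up: repeated degeneracy means the
                # input itself is pathological
                volumes[r] = convex_hull_volume(null_sample(X, model, stream))
        null_mean = float(volumes.mean())
        if ratio_mode == "null_mean":
            ratio = reduction_ratio(null_mean, observed)
        else:
            with np.errstate(divide="ignore", invalid="ignore"):
                ratio = float(np.mean(100.0 * (volumes - observed) / volumes))
        p = (1.0 + float((volumes <= observed).sum())) / (R + 1.0)
        results[model] = ModelResult(volumes, null_mean, float(ratio), float(p))
    return HypervolumeReport(observed, results, R, seed)
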