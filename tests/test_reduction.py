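"""Gower/PCoA/PCA machinery and KDE occupancy regions."""

import numpy as np
import pandas as pd
import pytest
from scipy import ndimage
from scipy.spatial.distance import pdist, squareform
from sklearn.decomposition import PCA

from phyloniche import (
    InvalidParameterError,
    SimulationConfig,
    ValidationError,
    build_functional_variables,
    gower_distance,
    kde_regions,
    pca_functional,
    pcoa,
    simulate_phylogeny,
    simulate_traits,
)
from phyloniche.io import TraitTable
from phyloniche.reduction import DistanceMatrix

from conftest import random_trait_table


def _table(values: dict, types: dict, dims: dict) -> TraitTable:
    data = pd.DataFrame(values)
    data.index = pd.Index([f"sp{i}" for i in range(len(data))], name="species")
    meta = pd.DataFrame(
        {"type": [types[t] for t in data.columns],
         "dimension": [dims[t] for t in data.columns]},
        index=pd.Index(data.columns, name="trait"),
    )
    return TraitTable(data, meta)


class TestGower:
    def test_identical_rows_distance_zero(self):
        t = _table(
            {"a": [1, 1], "b": [0, 0]},
            {"a": "binary", "b": "binary"},
            {"a": "habitat", "b": "habitat"},
        )
        d = gower_distance(t, "habitat")
        assert d.matrix[0, 1] == 0.0

    def test_binary_mismatch_mean(self):
        """4 binary traits with one mismatch: mean of {1,0,0,0} = 0.25."""
        t = _table(
            {f"b{i}": [1, 1] for i in range(4)} | {"b0": [1, 0]},
            {f"b{i}": "binary" for i in range(4)},
            {f"b{i}": "habitat" for i in range(4)},
        )
        d = gower_distance(t, "habitat")
        assert d.matrix[0, 1] == pytest.approx(0.25)

    def test_range_normalization(self):
        t = _table(
            {"q": [0.0, 5.0, 10.0]},
            {"q": "quantitative"},
            {"q": "trophic"},
        )
        d = gower_distance(t, "trophic")
        assert d.matrix[0, 2] == pytest.approx(1.0)
        assert d.matrix[0, 1] == pytest.approx(0.5)

    def test_zero_range_trait_dropped_with_warning(self):
        t = _table(
            {"q": [3.0, 3.0, 3.0], "b": [0, 1, 0]},
            {"q": "quantitative", "b": "binary"},
            {"q": "trophic", "b": "trophic"},
        )
        with pytest.warns(UserWarning, match="zero range"):
            d = gower_distance(t, "trophic")
        # only the binary trait contributes
        assert d.matrix[0, 1] == pytest.approx(1.0)

    def test_empty_dimension_rejected(self, toy_traits):
        with pytest.raises(InvalidParameterError, match="no traits"):
            gower_distance(toy_traits, "defense")

    def test_bounded_metric_properties_fuzz(self):
        for seed in range(10):
            t = random_trait_table(np.random.default_rng(seed))
            for dim in ("habitat", "trophic", "ecomorphology"):
                d = gower_distance(t, dim).matrix
                assert (d >= 0).all() and (d <= 1).all()
                assert np.allclose(d, d.T)
                assert np.allclose(np.diag(d), 0.0)


class TestPCoA:
    def test_collinear_points_single_axis(self):
        x = np.array([0.0, 1.0, 3.0, 6.0])
        D = np.abs(x[:, None] - x[None, :])
        res = pcoa(DistanceMatrix(D, ["a", "b", "c", "d"]))
        assert res.pct_variance[0] == pytest.approx(100.0)

    def test_equilateral_triangle_eigenstructure(self):
        D = np.ones((3, 3)) - np.eye(3)
        res = pcoa(DistanceMatrix(D, ["a", "b", "c"]))
        lam = res.eigenvalues[res.eigenvalues > 1e-12]
        assert len(lam) == 2
        assert lam[0] == pytest.approx(lam[1])
        assert res.pct_variance[0] == pytest.approx(50.0)

    def test_distance_reconstruction(self):
        rng = np.random.default_rng(0)
        pts = rng.normal(size=(8, 2))
        D = squareform(pdist(pts))
        res = pcoa(DistanceMatrix(D, [f"s{i}" for i in range(8)]))
        rec = squareform(pdist(res.scores.to_numpy()))
        assert np.allclose(rec, D, atol=1e-8)

    def test_matches_reference_implementation(self):
        """Independent oracle: scikit-bio's principal coordinates analysis."""
        from skbio.stats.ordination import pcoa as skbio_pcoa

        rng = np.random.default_rng(3)
        pts = rng.normal(size=(9, 4))
        D = squareform(pdist(pts))
        ours = pcoa(DistanceMatrix(D, [f"s{i}" for i in range(9)]))
        ref = skbio_pcoa(D, number_of_dimensions=4)
        assert np.allclose(
            ours.eigenvalues[:4], ref.eigvals.to_numpy()[:4], atol=1e-8
        )
        for j in range(4):
            a = ours.scores.to_numpy()[:, j]
            b = ref.samples.to_numpy()[:, j]
            assert np.allclose(np.abs(a), np.abs(b), atol=1e-8)

    def test_pcoa_of_euclidean_equals_pca(self):
        """Classical scaling of Euclidean distances reproduces PCA scores."""
        rng = np.random.default_rng(1)
        pts = rng.normal(size=(5, 3))
        D = squareform(pdist(pts))
        res = pcoa(DistanceMatrix(D, [f"s{i}" for i in range(5)]))
        ref = PCA(n_components=3).fit_transform(pts - pts.mean(axis=0))
        k = min(res.scores.shape[1], 3)
        assert np.allclose(
            np.abs(res.scores.to_numpy()[:, :k]), np.abs(ref[:, :k]), atol=1e-8
        )

    def test_all_zero_distances(self):
        with pytest.warns(UserWarning, match="all distances are zero"):
            res = pcoa(DistanceMatrix(np.zeros((3, 3)), ["a", "b", "c"]))
        assert res.scores.shape == (3, 1)
        assert (res.scores.to_numpy() == 0).all()


@pytest.fixture(scope="module")
def sim():
    cfg = SimulationConfig(n_species=30, n_deep_clades=2, seed=21)
    tree = simulate_phylogeny(cfg)
    return simulate_traits(tree, cfg)


class TestFunctionalVariables:

    def test_shape_and_columns(self, sim):
        red = build_functional_variables(sim)
        assert red.variables.shape == (30, 6)
        assert set(red.variables.columns) == {
            "habitat", "trophic", "life_history", "metabolic",
            "defense", "ecomorphology",
        }
        assert np.isfinite(red.variables.to_numpy()).all()

    def test_single_binary_trait_dimension_two_point_geometry(self):
        t = _table(
            {"b": [0, 1, 0, 1, 1], "q": [1.0, 2.0, 3.0, 4.0, 5.0]},
            {"b": "binary", "q": "quantitative"},
            {"b": "defense", "q": "trophic"},
        )
        red = build_functional_variables(t, dimensions=("defense", "trophic"))
        assert red.variables["defense"].round(9).nunique() == 2

    def test_relabeling_equivariance(self, sim):
        red = build_functional_variables(sim)
        perm = np.random.default_rng(0).permutation(len(sim.data))
        shuffled = TraitTable(sim.data.iloc[perm].copy(), sim.meta.copy())
        red2 = build_functional_variables(shuffled)
        pd.testing.assert_frame_equal(
            red2.variables, red.variables.iloc[perm], check_like=False
        )
        pd.testing.assert_frame_equal(red2.dimension_variance, red.dimension_variance)

    def test_missing_dimension_rejected(self, toy_traits):
        with pytest.raises(InvalidParameterError, match="without traits"):
            build_functional_variables(toy_traits)


class TestPCAFunctional:
    def test_contributions_sum_to_100(self):
        rng = np.random.default_rng(2)
        fv = pd.DataFrame(
            rng.normal(size=(20, 4)),
            index=[f"s{i}" for i in range(20)],
            columns=list("abcd"),
        )
        res = pca_functional(fv)
        assert np.allclose(res.contributions.sum(axis=0), 100.0, atol=1e-6)

    def test_two_perfectly_correlated_columns(self):
        x = np.arange(10, dtype=float)
        fv = pd.DataFrame(
            {"u": x, "v": 3.0 * x + 1.0}, index=[f"s{i}" for i in range(10)]
        )
        res = pca_functional(fv)
        assert res.pct_variance[0] == pytest.approx(100.0)
        assert res.contributions.iloc[:, 0].to_numpy() == pytest.approx([50.0, 50.0])

    def test_identity_covariance_limit(self):
        rng = np.random.default_rng(4)
        fv = pd.DataFrame(
            rng.standard_normal((10000, 6)),
            index=[f"s{i}" for i in range(10000)],
            columns=list("abcdef"),
        )
        res = pca_functional(fv)
        assert np.all(np.abs(res.eigenvalues - 1.0) < 0.1)
        assert np.all(np.abs(res.pct_variance - 100.0 / 6.0) < 2.0)

    def test_axis_scores_uncorrelated(self):
        rng = np.random.default_rng(5)
        fv = pd.DataFrame(
            rng.normal(size=(50, 5)),
            index=[f"s{i:02d}" for i in range(50)],
            columns=list("abcde"),
        )
        res = pca_functional(fv)
        corr = np.corrcoef(res.scores.to_numpy(), rowvar=False)
        off = corr[np.triu_indices(5, k=1)]
        assert np.all(np.abs(off) < 1e-8)

    def test_constant_column_rejected(self):
        fv = pd.DataFrame(
            {"a": [1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0], "b": [2.0] * 7},
            index=[f"s{i}" for i in range(7)],
        )
        with pytest.raises(ValidationError, match="'b'"):
            pca_functional(fv)

    def test_minor_contributors_not_tested(self):
        rng = np.random.default_rng(6)
        base = rng.normal(size=20)
        fv = pd.DataFrame(
            {
                "big1": base + 0.01 * rng.normal(size=20),
                "big2": base + 0.01 * rng.normal(size=20),
                "tiny": rng.normal(size=20),
            },
            index=[f"s{i}" for i in range(20)],
        )
        res = pca_functional(fv)
        small = res.contributions < 5.0
        assert res.variable_correlations.to_numpy()[small.to_numpy()].size > 0
        assert np.isnan(res.variable_correlations.to_numpy()[small.to_numpy()]).all()


class TestKDERegions:
    def test_nesting_and_coverage(self):
        rng = np.random.default_rng(7)
        pts = rng.normal(size=(200, 2))
        reg = kde_regions(pts, levels=(50, 95, 99))
        assert (reg.masks[50.0] <= reg.masks[95.0]).all()
        assert (reg.masks[95.0] <= reg.masks[99.0]).all()
        for L in (50.0, 95.0, 99.0):
            frac = reg.fraction_inside[L]
            assert frac >= L / 100.0
            # minimality: strictly above the threshold covers less than L%
            n = pts.shape[0]
            stricter = (reg.membership[f"in_{L:g}"].to_numpy().sum() - 1) / n
            assert stricter < L / 100.0 + 1e-12

    def test_bimodal_sample_splits_region(self):
        rng = np.random.default_rng(8)
        a = rng.normal(size=(150, 2)) * 0.3
        b = rng.normal(size=(150, 2)) * 0.3 + 8.0
        reg = kde_regions(np.vstack([a, b]), levels=(50,))
        _, n_components = ndimage.label(reg.masks[50.0])
        assert n_components >= 2

    def test_dimensionality_contract(self):
        rng = np.random.default_rng(9)
        with pytest.raises(InvalidParameterError):
            kde_regions(rng.normal(size=(50, 4)))
        with pytest.raises(InvalidParameterError):
            kde_regions(rng.normal(size=(1, 2)))
        reg = kde_regions(rng.normal(size=(40, 3)), levels=(90,))
        assert reg.density.ndim == 3
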