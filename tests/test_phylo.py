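"""PSV, its permutation test, phylogenetic fuzzy weighting and PCPS."""

import numpy as np
import pandas as pd
import pytest

from phyloniche import (
    GROUP_LABELS,
    GroupAssignment,
    InvalidParameterError,
    SimulationConfig,
    fuzzy_weighting,
    pcps,
    phylo_correlation,
    psv,
    psv_permutation_test,
    simulate_groups,
    simulate_phylogeny,
)
from phyloniche.io import tree_from_string
from phyloniche.phylo import MatrixP, sqrt_bray_curtis
from phyloniche.reduction import pcoa


def _assignment(membership: dict[str, list[str]], species: list[str]) -> GroupAssignment:
    m = pd.DataFrame(0, index=pd.Index(species, name="species"), columns=list(GROUP_LABELS))
    for label, members in membership.items():
        m.loc[members, label] = 1
    return GroupAssignment(m)


class TestPhyloCorrelation:
    def test_star_tree_identity(self, star_tree_8):
        C = phylo_correlation(star_tree_8)
        assert np.allclose(C.matrix, np.eye(8))

    def test_hand_checkable_tree(self):
        C = phylo_correlation(tree_from_string("((A:1,B:1):1,C:2);"))
        i = {s: k for k, s in enumerate(C.ids)}
        assert C.matrix[i["A"], i["B"]] == pytest.approx(0.5)
        assert C.matrix[i["A"], i["C"]] == pytest.approx(0.0)
        assert np.allclose(np.diag(C.matrix), 1.0)

    def test_positive_semidefinite_on_random_trees(self):
        for seed in range(5):
            cfg = SimulationConfig(n_species=25, n_deep_clades=2, seed=seed)
            C = phylo_correlation(simulate_phylogeny(cfg))
            assert np.linalg.eigvalsh(C.matrix).min() >= -1e-9

    def test_zero_depth_tip_rejected(self):
        with pytest.raises(Exception, match="zero root-to-tip depth"):
            phylo_correlation(tree_from_string("(A:0,B:1);"))


class TestPSV:
    def test_star_phylogeny_is_one(self, star_tree_8):
        C = phylo_correlation(star_tree_8)
        assert psv(C) == pytest.approx(1.0)

    def test_all_ones_correlation_is_zero(self):
        tree = tree_from_string("((A:0,B:0,C:0,D:0,E:0,F:0):1);")
        C = phylo_correlation(tree)
        assert np.allclose(C.matrix, 1.0)
        assert psv(C) == pytest.approx(0.0)

    def test_pair_closed_form(self):
        # for n=2, PSV = 1 - c
        tree = tree_from_string("((A:0.5,B:0.5):0.5);")
        C = phylo_correlation(tree)
        assert psv(C, ["A", "B"]) == pytest.approx(0.5)

    def test_bounded_and_scale_invariant(self):
        rng = np.random.default_rng(0)
        for seed in range(5):
            cfg = SimulationConfig(n_species=20, n_deep_clades=2, seed=seed)
            tree = simulate_phylogeny(cfg)
            C = phylo_correlation(tree)
            members = list(rng.choice(C.ids, size=6, replace=False))
            v = psv(C, members)
            assert 0.0 <= v <= 1.0
            # uniform branch-length scaling leaves the correlation unchanged
            scaled = tree.clone(depth=1)
            for edge in scaled.preorder_edge_iter():
                if edge.length is not None:
                    edge.length *= 7.3
            assert psv(phylo_correlation(scaled), members) == pytest.approx(v)

    def test_singleton_rejected(self, star_tree_8):
        C = phylo_correlation(star_tree_8)
        with pytest.raises(InvalidParameterError):
            psv(C, ["t1"])


class TestPSVPermutationTest:
    def test_whole_pool_group_degenerates_to_random(self, star_tree_8):
        C = phylo_correlation(star_tree_8)
        ga = _assignment({GROUP_LABELS[0]: list(C.ids)}, list(C.ids))
        report = psv_permutation_test(ga, C, R=199, seed=0)
        assert np.allclose(report.null_values, report.observed_mean)
        assert report.verdict == "random"

    def test_observed_statistic_matches_groupwise_recount(self, two_clade_tree):
        cfg = SimulationConfig(n_species=40, n_deep_clades=2, seed=11)
        ga = simulate_groups(two_clade_tree, cfg, n_groups=5, group_sizes=6)
        C = phylo_correlation(two_clade_tree)
        report = psv_permutation_test(ga, C, R=199, seed=1)
        recount = np.mean(
            [psv(C, ga.members(l)) for l in GROUP_LABELS[:5]]
        )
        assert report.observed_mean == pytest.approx(recount, abs=1e-12)
        assert report.lower <= report.null_mean <= report.upper

    def test_determinism(self, two_clade_tree):
        cfg = SimulationConfig(n_species=40, n_deep_clades=2, seed=11)
        ga = simulate_groups(two_clade_tree, cfg)
        C = phylo_correlation(two_clade_tree)
        a = psv_permutation_test(ga, C, R=199, seed=5)
        b = psv_permutation_test(ga, C, R=199, seed=5)
        assert np.array_equal(a.null_values, b.null_values)
        assert a.verdict == b.verdict


class TestFuzzyWeighting:
    def test_star_tree_reduces_to_row_standardized_incidence(self, star_tree_8):
        """On a star tree Q is the identity, so P is just the
        row-standardized incidence (hand-checkable toy)."""
        species = [f"t{i}" for i in range(1, 9)]
        ga = _assignment(
            {GROUP_LABELS[0]: ["t1", "t2"], GROUP_LABELS[1]: ["t3", "t4", "t5"]},
            species,
        )
        P = fuzzy_weighting(star_tree_8, ga)
        row0 = P.values.loc[GROUP_LABELS[0]]
        assert row0.loc["t1"] == pytest.approx(0.5)
        assert row0.loc["t2"] == pytest.approx(0.5)
        assert row0.loc["t3"] == pytest.approx(0.0)
        row1 = P.values.loc[GROUP_LABELS[1]]
        assert row1.loc["t3"] == pytest.approx(1.0 / 3.0)

    def test_identical_membership_identical_rows(self, two_clade_tree):
        species = sorted(l.taxon.label for l in two_clade_tree.leaf_node_iter())
        members = species[:6]
        ga = _assignment(
            {GROUP_LABELS[0]: members, GROUP_LABELS[1]: members,
             GROUP_LABELS[2]: species[6:12]},
            species,
        )
        P = fuzzy_weighting(two_clade_tree, ga)
        assert np.allclose(
            P.values.loc[GROUP_LABELS[0]], P.values.loc[GROUP_LABELS[1]]
        )
        d = sqrt_bray_curtis(P)
        i = list(P.values.index)
        assert d.matrix[i.index(GROUP_LABELS[0]), i.index(GROUP_LABELS[1])] == pytest.approx(0.0)

    def test_rows_sum_to_one(self, two_clade_tree):
        cfg = SimulationConfig(n_species=40, n_deep_clades=2, seed=11)
        ga = simulate_groups(two_clade_tree, cfg)
        P = fuzzy_weighting(two_clade_tree, ga)
        assert np.allclose(P.values.sum(axis=1), 1.0, atol=1e-9)

    def test_species_off_tree_dropped_with_warning(self, star_tree_8):
        species = [f"t{i}" for i in range(1, 9)] + ["ghost"]
        ga = _assignment({GROUP_LABELS[0]: ["t1", "t2"],
                          GROUP_LABELS[1]: ["t3", "ghost"]}, species)
        with pytest.warns(UserWarning, match="absent from the tree"):
            P = fuzzy_weighting(star_tree_8, ga)
        assert "ghost" not in P.values.columns


class TestPCPS:
    def test_sqrt_bray_curtis_toy_matrix(self):
        """Hand-computed square-rooted Bray–Curtis on a 3-group x 4-species P."""
        P = MatrixP(pd.DataFrame(
            [[0.5, 0.5, 0.0, 0.0],
             [0.0, 0.5, 0.5, 0.0],
             [0.25, 0.25, 0.25, 0.25]],
            index=["g1", "g2", "g3"],
            columns=["a", "b", "c", "d"],
        ))
        d = sqrt_bray_curtis(P)
        # BC(g1,g2) = 1 - 2*min_sum = 1 - 2*0.5*... computed by hand:
        # shared = min(.5,0)+min(.5,.5)+min(0,.5)+0 = 0.5 -> BC = 1-2*0.5/2 = 0.5
        assert d.matrix[0, 1] == pytest.approx(np.sqrt(0.5), abs=1e-12)
        # shared(g1,g3) = 0.25+0.25 = 0.5 -> BC = 0.5
        assert d.matrix[0, 2] == pytest.approx(np.sqrt(0.5), abs=1e-12)
        assert (d.matrix <= 1.0 + 1e-12).all()

    def test_variance_non_increasing(self, two_clade_tree):
        cfg = SimulationConfig(n_species=40, n_deep_clades=2, seed=11)
        ga = simulate_groups(two_clade_tree, cfg, n_groups=6)
        result = pcps(fuzzy_weighting(two_clade_tree, ga))
        pct = result.pct_variance
        assert all(pct[i] >= pct[i + 1] - 1e-12 for i in range(len(pct) - 1))
        assert result.retained == [bool(v > 10.0) for v in pct]

    def test_basal_split_separates_clade_pure_groups(self):
        cfg = SimulationConfig(n_species=40, n_deep_clades=2, conservatism=1.0, seed=13)
        tree = simulate_phylogeny(cfg)
        ga = simulate_groups(tree, cfg, n_groups=6, group_sizes=8)
        result = pcps(fuzzy_weighting(tree, ga))
        # groups alternate focal clades 0,1,0,1,...
        scores = result.scores["axis1"]
        clade0 = scores.iloc[0::2].to_numpy()
        clade1 = scores.iloc[1::2].to_numpy()
        assert (np.sign(clade0) == np.sign(clade0[0])).all()
        assert (np.sign(clade1) == -np.sign(clade0[0])).all()

    def test_star_tree_equals_compositional_pcoa(self, star_tree_8):
        """With Q = identity, PCPS is the ordinary PCoA of the
        row-standardized incidence under the same dissimilarity."""
        species = [f"t{i}" for i in range(1, 9)]
        ga = _assignment(
            {GROUP_LABELS[0]: ["t1", "t2"],
             GROUP_LABELS[1]: ["t3", "t4", "t5"],
             GROUP_LABELS[2]: ["t1", "t6", "t7"]},
            species,
        )
        result = pcps(fuzzy_weighting(star_tree_8, ga))
        W = ga.membership.loc[species].T.astype(float)
        W = W.loc[(W.sum(axis=1) > 0)]
        W = W.div(W.sum(axis=1), axis=0)
        ref = pcoa(sqrt_bray_curtis(MatrixP(W)))
        assert np.allclose(
            result.ordination.eigenvalues, ref.eigenvalues, atol=1e-10
        )
        assert np.allclose(
            np.abs(result.scores.to_numpy()), np.abs(ref.scores.to_numpy()), atol=1e-10
        )

    def test_identical_rows_rejected(self, star_tree_8):
        species = [f"t{i}" for i in range(1, 9)]
        ga = _assignment(
            {GROUP_LABELS[0]: ["t1", "t2"], GROUP_LABELS[1]: ["t1", "t2"],
             GROUP_LABELS[2]: ["t1", "t2"]},
            species,
        )
        with pytest.raises(Exception, match="identical"):
            pcps(fuzzy_weighting(star_tree_8, ga))
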