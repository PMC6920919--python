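"""Bray–Curtis, UPGMA dendrograms, similarity cuts and SIMPER."""

import numpy as np
import pandas as pd
import pytest
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from phyllonet import (
    CommunityError,
    bray_curtis,
    between_group_simper,
    cut_clusters,
    simper,
    upgma_cluster,
)

from conftest import make_table


class TestBrayCurtis:
    def test_identical_samples_zero(self):
        d = bray_curtis(make_table([[3, 3], [7, 7]]))
        assert d.iloc[0, 1] == 0.0

    def test_disjoint_supports_one(self):
        d = bray_curtis(make_table([[3, 0], [0, 7]]))
        assert d.iloc[0, 1] == 1.0

    def test_hand_computed_value(self):
        d = bray_curtis(make_table([[1, 0], [1, 1], [0, 1]]))
        assert d.iloc[0, 1] == pytest.approx(0.5)

    def test_common_rescaling_invariance(self):
        rng = np.random.default_rng(0)
        counts = rng.integers(0, 40, size=(10, 4))
        counts[0] += 1
        d1 = bray_curtis(make_table(counts))
        d2 = bray_curtis(make_table(counts * 3))
        pd.testing.assert_frame_equal(d1, d2)

    def test_bounded_and_symmetric(self, default_community):
        table, _, _ = default_community
        d = bray_curtis(table)
        arr = d.to_numpy()
        assert ((arr >= 0) & (arr <= 1)).all()
        assert np.allclose(arr, arr.T)
        assert np.allclose(np.diag(arr), 0)

    def test_all_zero_sample_rejected(self):
        with pytest.raises(CommunityError):
            bray_curtis(make_table([[1, 0], [2, 0]]))


def cophenetic_of(tree, labels):
    """Height at which each leaf pair first merges, as a condensed vector."""
    heights = {}
    for m in tree.merges:
        for a in m.left:
            for b in m.right:
                heights[frozenset((a, b))] = m.height
    return np.array(
        [
            heights[frozenset((labels[i], labels[j]))]
            for i in range(len(labels))
            for j in range(i + 1, len(labels))
        ]
    )


class TestUpgma:
    def test_two_samples(self):
        d = pd.DataFrame([[0, 0.4], [0.4, 0]], index=["A", "B"], columns=["A", "B"])
        tree = upgma_cluster(d)
        assert len(tree.merges) == 1
        assert tree.merges[0].height == pytest.approx(0.4)

    def test_three_samples_hand_computed(self):
        d = pd.DataFrame(
            [[0, 0.2, 0.6], [0.2, 0, 0.6], [0.6, 0.6, 0]],
            index=list("ABC"), columns=list("ABC"),
        )
        tree = upgma_cluster(d)
        assert tree.merges[0].members == ("A", "B")
        assert tree.merges[0].height == pytest.approx(0.2)
        assert tree.merges[1].height == pytest.approx(0.6)

    def test_matches_scipy_average_linkage(self):
        # independent oracle: scipy's UPGMA on random (tie-free) matrices,
        # compared through cophenetic distances
        rng = np.random.default_rng(0)
        for trial in range(100):
            n = 5
            condensed = rng.uniform(0.05, 1.0, size=n * (n - 1) // 2)
            labels = [f"S{i}" for i in range(n)]
            d = pd.DataFrame(squareform(condensed), index=labels, columns=labels)
            tree = upgma_cluster(d)
            z = hierarchy.linkage(condensed, method="average")
            expected = hierarchy.cophenet(z)
            assert np.allclose(cophenetic_of(tree, labels), expected, atol=1e-10)

    def test_input_order_invariance(self):
        rng = np.random.default_rng(1)
        n = 6
        labels = [f"S{i}" for i in range(n)]
        d = pd.DataFrame(
            squareform(rng.uniform(0.1, 1, size=n * (n - 1) // 2)),
            index=labels, columns=labels,
        )
        perm = list(np.array(labels)[rng.permutation(n)])
        tree1 = upgma_cluster(d)
        tree2 = upgma_cluster(d.loc[perm, perm])
        assert np.allclose(
            cophenetic_of(tree1, labels), cophenetic_of(tree2, labels), atol=1e-12
        )

    def test_asymmetric_rejected(self):
        d = pd.DataFrame([[0, 0.5], [0.2, 0]], index=["A", "B"], columns=["A", "B"])
        with pytest.raises(CommunityError):
            upgma_cluster(d)

    def test_newick_exports_ultrametric_tree(self):
        import dendropy

        d = pd.DataFrame(
            [[0, 0.2, 0.6], [0.2, 0, 0.6], [0.6, 0.6, 0]],
            index=list("ABC"), columns=list("ABC"),
        )
        nwk = upgma_cluster(d).to_newick()
        tree = dendropy.Tree.get(data=nwk, schema="newick")
        depths = {
            leaf.taxon.label: leaf.distance_from_root()
            for leaf in tree.leaf_node_iter()
        }
        assert depths["A"] == pytest.approx(0.3)  # root height 0.6 / 2
        assert depths["C"] == pytest.approx(0.3)


class TestCuts:
    @pytest.fixture
    def tree3(self):
        d = pd.DataFrame(
            [[0, 0.2, 0.6], [0.2, 0, 0.6], [0.6, 0.6, 0]],
            index=list("ABC"), columns=list("ABC"),
        )
        return upgma_cluster(d)

    def test_cut_near_zero_similarity_is_root(self, tree3):
        assert cut_clusters(tree3, 1e-9).nunique() == 1

    def test_cut_above_all_merges_gives_singletons(self, tree3):
        assert cut_clusters(tree3, 90).nunique() == 3

    def test_cut_at_fifty_percent(self, tree3):
        assign = cut_clusters(tree3, 50)
        assert assign["A"] == assign["B"]
        assert assign["A"] != assign["C"]

    def test_invalid_level_rejected(self, tree3):
        with pytest.raises(CommunityError):
            cut_clusters(tree3, 0)


class TestSimper:
    def two_cluster_assignment(self, samples):
        return pd.Series("X", index=samples, name="cluster")

    def test_identical_pair_decomposition(self):
        table = make_table([[50, 50], [50, 50]])
        res = simper(table, self.two_cluster_assignment(["S0", "S1"]))
        assert res.average_similarity["X"] == pytest.approx(100.0)
        contrib = res.contributions["X"]["contribution"]
        assert contrib.loc["OTU0"] == pytest.approx(50.0)
        assert contrib.loc["OTU1"] == pytest.approx(50.0)

    def test_hand_computed_decomposition(self):
        # x=(4,0,4), y=(0,4,4): similarity 50, contributions (0, 0, 50)
        table = make_table([[4, 0], [0, 4], [4, 4]])
        res = simper(table, self.two_cluster_assignment(["S0", "S1"]))
        assert res.average_similarity["X"] == pytest.approx(50.0)
        contrib = res.contributions["X"]["contribution"]
        assert contrib.loc["OTU0"] == 0.0
        assert contrib.loc["OTU2"] == pytest.approx(50.0)

    def test_conservation_identity(self):
        rng = np.random.default_rng(0)
        for trial in range(20):
            counts = rng.integers(0, 60, size=(25, 4))
            counts[0] += 1
            table = make_table(counts)
            res = simper(table, self.two_cluster_assignment(table.sample_ids))
            total = res.contributions["X"]["contribution"].sum()
            assert total == pytest.approx(res.average_similarity["X"], abs=1e-9)

    def test_cumulative_reaches_cutoff(self):
        rng = np.random.default_rng(1)
        table = make_table(rng.integers(0, 60, size=(30, 3)) + 1)
        res = simper(table, self.two_cluster_assignment(table.sample_ids), cutoff=0.9)
        chosen = res.discriminating["X"]
        cum = res.contributions["X"].loc[chosen, "pct_of_total"].sum()
        assert cum >= 90.0

    def test_singleton_cluster_skipped_with_warning(self):
        table = make_table([[5, 5, 5], [2, 2, 2]])
        clusters = pd.Series(["X", "X", "Y"], index=table.sample_ids)
        with pytest.warns(UserWarning, match="Y"):
            res = simper(table, clusters)
        assert "Y" not in res.average_similarity

    def test_solely_responsible_is_set_difference(self):
        table = make_table([[50, 50, 0, 0], [50, 50, 40, 40], [0, 0, 60, 60]])
        clusters = pd.Series(["X", "X", "Y", "Y"], index=table.sample_ids)
        res = simper(table, clusters)
        assert "OTU0" in res.solely_responsible("X")
        assert "OTU1" not in res.solely_responsible("X")

    def test_between_group_conservation(self):
        rng = np.random.default_rng(2)
        counts = rng.integers(0, 60, size=(15, 4)) + 1
        table = make_table(counts)
        clusters = pd.Series(["X", "X", "Y", "Y"], index=table.sample_ids)
        total, frame = between_group_simper(table, clusters, "X", "Y")
        d = bray_curtis(table)
        mean_d = 100 * np.mean(
            [d.loc[a, b] for a in ["S0", "S1"] for b in ["S2", "S3"]]
        )
        assert total == pytest.approx(mean_d, abs=1e-9)
        assert frame["contribution"].sum() == pytest.approx(total, abs=1e-9)
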