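"""Linkage, tree cuts, CH index and cluster-count selection against oracles."""

import numpy as np
import pandas as pd
import pytest

from oracles import ch_oracle, complete_linkage_heights_oracle, welch_oracle
from pathosig.cluster import (
    calinski_harabasz,
    cluster_contrast,
    cluster_samples,
    cut_tree,
    hierarchical_cluster,
    linkage_to_newick,
    select_cluster_count,
)


class TestLinkage:
    def test_three_point_line(self):
        Z = hierarchical_cluster(np.array([[0.0], [1.0], [10.0]]))
        np.testing.assert_allclose(Z[:, 2], [1.0, 10.0])

    def test_duplicate_points_merge_at_zero(self):
        Z = hierarchical_cluster(np.array([[1.0, 2.0], [1.0, 2.0], [5.0, 5.0]]))
        assert Z[0, 2] == 0.0

    def test_two_samples(self):
        Z = hierarchical_cluster(np.array([[0.0, 0.0], [3.0, 4.0]]))
        assert Z.shape == (1, 4)
        assert Z[0, 2] == pytest.approx(5.0)

    def test_missing_value_names_cell(self):
        X = pd.DataFrame({"a": [1.0, np.nan]}, index=["s1", "s2"])
        with pytest.raises(ValueError, match="s2"):
            hierarchical_cluster(X)

    def test_heights_match_brute_force_oracle(self, rng):
        for _ in range(40):
            n = int(rng.integers(3, 13))
            X = rng.normal(size=(n, int(rng.integers(1, 4))))
            Z = hierarchical_cluster(X)
            np.testing.assert_allclose(
                sorted(Z[:, 2]), sorted(complete_linkage_heights_oracle(X)), atol=1e-10
            )


class TestCutTree:
    def test_extremes(self):
        X = np.arange(5, dtype=float)[:, None]
        Z = hierarchical_cluster(X)
        assert len(np.unique(cut_tree(Z, 5))) == 5
        assert len(np.unique(cut_tree(Z, 1))) == 1

    def test_two_cluster_cut_of_line(self):
        Z = hierarchical_cluster(np.array([[0.0], [1.0], [10.0]]))
        labels = cut_tree(Z, 2)
        assert labels[0] == labels[1]
        assert labels[0] != labels[2]

    def test_out_of_range(self):
        Z = hierarchical_cluster(np.array([[0.0], [1.0], [10.0]]))
        with pytest.raises(ValueError):
            cut_tree(Z, 4)
        with pytest.raises(ValueError):
            cut_tree(Z, 0)


class TestCHIndex:
    def test_hand_example_is_exact(self):
        X = np.array([[0.0], [1.0], [10.0], [11.0]])
        assert calinski_harabasz(X, [0, 0, 1, 1]) == pytest.approx(200.0, abs=1e-12)

    def test_identical_point_clusters_give_infinity(self, caplog):
        X = np.array([[1.0], [1.0], [5.0], [5.0]])
        with caplog.at_level("WARNING", logger="pathosig.cluster"):
            assert calinski_harabasz(X, [0, 0, 1, 1]) == np.inf

    def test_single_cluster_rejected(self):
        with pytest.raises(ValueError):
            calinski_harabasz(np.array([[0.0], [1.0], [2.0]]), [0, 0, 0])

    def test_matches_definition_oracle(self, rng):
        for _ in range(50):
            n = int(rng.integers(4, 20))
            X = rng.normal(size=(n, int(rng.integers(1, 5))))
            k = int(rng.integers(2, n - 1))
            labels = rng.integers(0, k, size=n)
            if len(np.unique(labels)) < 2:
                continue
            assert calinski_harabasz(X, labels) == pytest.approx(
                ch_oracle(X, labels), rel=1e-10
            )

    def test_matches_sklearn(self, rng):
        from sklearn.metrics import calinski_harabasz_score

        X = rng.normal(size=(30, 4))
        labels = rng.integers(0, 3, size=30)
        assert calinski_harabasz(X, labels) == pytest.approx(
            calinski_harabasz_score(X, labels), rel=1e-10
        )

    def test_label_permutation_invariance(self, rng):
        X = rng.normal(size=(20, 3))
        labels = rng.integers(0, 4, size=20)
        relabeled = (labels + 7) % 11  # injective on 0..3
        assert calinski_harabasz(X, labels) == pytest.approx(
            calinski_harabasz(X, relabeled), rel=1e-12
        )


class TestSelectClusterCount:
    @pytest.mark.parametrize("k_true", [2, 3])
    def test_separated_blobs_recovered(self, k_true):
        """Blobs separated by 15 within-blob SDs in 3 dimensions: CH picks
        the planted count.  (In 1-D, splitting a tight blob into m slices
        shrinks W by ~m^2 and CH keeps rising with k, so multi-dimensional
        profiles are the regime where CH selection is meaningful.)"""
        from pathosig.evaluation import BlobDesign, sample_blobs

        rng = np.random.default_rng(1234)
        X = sample_blobs(BlobDesign(n_clusters=k_true), rng)
        selected, curve, _ = select_cluster_count(X)
        assert selected == k_true
        assert selected == max(curve, key=lambda k: (curve[k], -k))

    def test_singleton_range(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(10, 2))
        selected, curve, _ = select_cluster_count(X, [2])
        assert selected == 2 and set(curve) == {2}

    def test_empty_range_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            select_cluster_count(np.zeros((5, 1)), [])

    def test_cluster_samples_result_structure(self, rng):
        X = pd.DataFrame(
            rng.normal(size=(12, 3)), index=[f"S{i}" for i in range(12)]
        )
        result = cluster_samples(X, range(2, 5))
        assert result.selected_k in result.ch_curve
        assert result.ch_curve[result.selected_k] == max(result.ch_curve.values())
        for k, labels in result.labels.items():
            assert len(np.unique(labels)) == k
        assert sorted(result.leaf_order()) == sorted(X.index)


class TestClusterContrast:
    def test_identical_clusters_give_zero_t(self, rng):
        base = rng.normal(size=(3, 2))
        mat = pd.DataFrame(
            np.vstack([base, base]),
            index=[f"a{i}" for i in range(3)] + [f"b{i}" for i in range(3)],
            columns=["org1", "org2"],
        )
        out = cluster_contrast(mat, [f"a{i}" for i in range(3)], [f"b{i}" for i in range(3)])
        np.testing.assert_allclose(out["t"], 0.0, atol=1e-12)
        np.testing.assert_allclose(out["logfc"], 0.0, atol=1e-12)

    def test_logfc_is_mean_difference_and_antisymmetric(self, rng):
        mat = pd.DataFrame(
            np.vstack([rng.normal(3, 1, size=(5, 1)), rng.normal(1, 1, size=(5, 1))]),
            index=[f"s{i}" for i in range(10)],
            columns=["org"],
        )
        a, b = [f"s{i}" for i in range(5)], [f"s{i}" for i in range(5, 10)]
        fwd = cluster_contrast(mat, a, b)
        rev = cluster_contrast(mat, b, a)
        assert fwd["logfc"][0] == pytest.approx(
            mat.loc[a, "org"].mean() - mat.loc[b, "org"].mean()
        )
        assert rev["t"][0] == pytest.approx(-fwd["t"][0])
        assert rev["logfc"][0] == pytest.approx(-fwd["logfc"][0])

    def test_matches_welch_oracle(self, rng):
        mat = pd.DataFrame(
            rng.normal(size=(12, 4)),
            index=[f"s{i}" for i in range(12)],
            columns=[f"org{i}" for i in range(4)],
        )
        a, b = [f"s{i}" for i in range(6)], [f"s{i}" for i in range(6, 12)]
        out = cluster_contrast(mat, a, b).set_index("organism")
        for org in mat.columns:
            t_ref, p_ref = welch_oracle(
                mat.loc[a, org], mat.loc[b, org], alternative="two-sided"
            )
            assert out.loc[org, "t"] == pytest.approx(t_ref, abs=1e-10)
            assert out.loc[org, "p"] == pytest.approx(p_ref, abs=1e-10)

    def test_small_cluster_rejected(self, rng):
        mat = pd.DataFrame(rng.normal(size=(4, 1)), index=list("abcd"), columns=["o"])
        with pytest.raises(ValueError, match="at least 2"):
            cluster_contrast(mat, ["a"], ["b", "c", "d"])


def test_newick_heights_reflect_merge_structure():
    Z = hierarchical_cluster(np.array([[0.0], [1.0], [10.0]]))
    newick = linkage_to_newick(Z, ["s0", "s1", "s2"])
    assert newick.endswith(";")
    assert {"s0", "s1", "s2"} <= set(newick.replace("(", " ").replace(")", " ").replace(",", " ").replace(":", " ").split())
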