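import numpy as np
import pandas as pd
import pytest

from divpower.beta import (
    bray_curtis,
    beta_distance,
    group_centroid_distances,
    jaccard,
    unweighted_unifrac,
    weighted_unifrac,
)
from divpower.community import (
    CountTable,
    GroupDesign,
    ValidationError,
    as_distance_matrix,
    read_tree,
)
from divpower.simulate import random_tree
from conftest import random_table


def table_from(rows, ids=None, features=None):
    rows = np.atleast_2d(np.asarray(rows, dtype=float))
    ids = ids or [f"s{i}" for i in range(rows.shape[0])]
    features = features or [f"f{j}" for j in range(rows.shape[1])]
    return CountTable(pd.DataFrame(rows, index=ids, columns=features))


class TestBrayCurtis:
    def test_identical_samples_zero(self):
        t = table_from([[1, 2, 3], [1, 2, 3]])
        assert bray_curtis(t)["s0", "s1"] == 0.0

    def test_disjoint_samples_one(self):
        t = table_from([[5, 0], [0, 3]])
        assert bray_curtis(t)["s0", "s1"] == 1.0

    def test_formula_example(self):
        t = table_from([[2, 0, 6], [1, 3, 4]])
        assert bray_curtis(t)["s0", "s1"] == pytest.approx(0.375)

    def test_all_zero_sample_rejected(self):
        t = table_from([[1, 1], [0, 0]])
        with pytest.raises(ValidationError, match="all-zero"):
            bray_curtis(t)

    def test_not_invariant_to_total_rescaling(self):
        t = table_from([[10, 0], [1, 1]])
        t2 = table_from([[100, 0], [1, 1]])
        assert bray_curtis(t)["s0", "s1"] != bray_curtis(t2)["s0", "s1"]


class TestJaccard:
    def test_half_shared(self):
        t = table_from([[1, 1, 1, 0], [0, 2, 9, 3]])
        assert jaccard(t)["s0", "s1"] == pytest.approx(0.5)

    def test_identical_presence_zero(self):
        t = table_from([[1, 5, 0], [9, 1, 0]])
        assert jaccard(t)["s0", "s1"] == 0.0

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_binary_identity_with_bray_curtis(self, seed):
        # on presence/absence data J = 2 BC / (1 + BC)
        rng = np.random.default_rng(seed)
        t = table_from((rng.random((6, 20)) < 0.5).astype(float))
        J = jaccard(t).data
        BC = bray_curtis(t).data
        np.testing.assert_allclose(J, 2 * BC / (1 + BC), atol=1e-12)


from tests_beta_oracle import brute_force_unifrac_pair


class TestUniFrac:
    def test_identical_presence_zero(self, three_leaf_tree):
        t = table_from([[1, 2, 0], [5, 1, 0]], features=["A", "B", "C"])
        assert unweighted_unifrac(t, three_leaf_tree)["s0", "s1"] == 0.0

    def test_opposite_sides_of_root_is_one(self):
        tree = read_tree("((A:1,B:2):0.5,(C:3,D:1):0.25):0;")
        t = table_from([[1, 1, 0, 0], [0, 0, 1, 1]],
                       features=["A", "B", "C", "D"])
        assert unweighted_unifrac(t, tree)["s0", "s1"] == pytest.approx(1.0)

    def test_weighted_star_tree_concentrated(self):
        tree = read_tree("(A:1,B:1,C:1):0;")
        t = table_from([[7, 0, 0], [0, 0, 3]], features=["A", "B", "C"])
        raw = weighted_unifrac(t, tree)["s0", "s1"]
        norm = weighted_unifrac(t, tree, normalized=True)["s0", "s1"]
        assert raw == pytest.approx(2.0)
        assert norm == pytest.approx(1.0)

    def test_weighted_identical_profiles_zero(self, three_leaf_tree):
        t = table_from([[2, 4, 6], [1, 2, 3]], features=["A", "B", "C"])
        assert weighted_unifrac(t, three_leaf_tree)["s0", "s1"] == \
            pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_matches_brute_force_edge_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        n_leaves = int(rng.integers(4, 13))
        ids = [f"L{i}" for i in range(n_leaves)]
        tree = random_tree(ids, rng)
        t = random_table(rng, 5, n_leaves)
        t = CountTable(t.data.set_axis(ids, axis=1))
        X = t.values
        uf = unweighted_unifrac(t, tree)
        wf = weighted_unifrac(t, tree)
        for i in range(5):
            for j in range(i + 1, 5):
                u_ref, w_ref = brute_force_unifrac_pair(tree, X, ids, i, j)
                assert uf.data[i, j] == pytest.approx(u_ref, abs=1e-10)
                assert wf.data[i, j] == pytest.approx(w_ref, abs=1e-10)

    def test_unweighted_ignores_abundances(self, base_community):
        table, tree = base_community
        sub = CountTable(table.data.iloc[:8])
        binary = CountTable((sub.data > 0).astype(float))
        np.testing.assert_allclose(
            unweighted_unifrac(sub, tree).data,
            unweighted_unifrac(binary, tree).data, atol=1e-12)

    def test_weighted_invariant_to_sample_totals(self, base_community):
        table, tree = base_community
        sub = CountTable(table.data.iloc[:6])
        scaled = CountTable(sub.data * np.array([1, 10, 3, 7, 2, 5])[:, None])
        np.testing.assert_allclose(
            weighted_unifrac(sub, tree).data,
            weighted_unifrac(scaled, tree).data, atol=1e-10)

    def test_skbio_agreement(self, base_community):
        from skbio.diversity import beta_diversity

        table, tree = base_community
        sub = CountTable(table.data.iloc[:6])
        ref = beta_diversity(
            "weighted_unifrac", sub.values, ids=sub.sample_ids,
            taxa=sub.feature_ids, tree=tree)
        np.testing.assert_allclose(weighted_unifrac(sub, tree).data,
                                   ref.data, atol=1e-10)
        ref_u = beta_diversity(
            "unweighted_unifrac", (sub.values > 0).astype(int),
            ids=sub.sample_ids, taxa=sub.feature_ids, tree=tree)
        np.testing.assert_allclose(unweighted_unifrac(sub, tree).data,
                                   ref_u.data, atol=1e-10)


class TestMetricBounds:
    @pytest.mark.parametrize(
        "metric", ["braycurtis", "jaccard", "unweighted_unifrac"])
    def test_unit_interval(self, metric, base_community):
        table, tree = base_community
        sub = CountTable(table.data.iloc[:10])
        dm = beta_distance(sub, metric, tree=tree)
        assert dm.data.min() >= 0.0
        assert dm.data.max() <= 1.0 + 1e-12

    def test_dispatch_rejects_unknown(self, tiny_table):
        with pytest.raises(ValidationError, match="unknown beta metric"):
            beta_distance(tiny_table, "euclidean")

    def test_unifrac_requires_tree(self, tiny_table):
        with pytest.raises(ValidationError, match="requires"):
            beta_distance(tiny_table, "weighted_unifrac")


class TestGroupCentroidDistances:
    def test_identical_samples_zero(self):
        dm = as_distance_matrix(np.zeros((2, 2)), ["a", "b"])
        design = GroupDesign({"a": "g", "b": "g"})
        dist, means = group_centroid_distances(dm, design)
        assert dist.tolist() == [0.0, 0.0]
        assert means["g"] == 0.0

    def test_one_dimensional_pair(self):
        dm = as_distance_matrix([[0, 2], [2, 0]], ["a", "b"])
        design = GroupDesign({"a": "g", "b": "g"})
        dist, _ = group_centroid_distances(dm, design)
        np.testing.assert_allclose(dist.to_numpy(), [1.0, 1.0], atol=1e-10)

    def test_euclidean_matches_coordinate_oracle(self):
        rng = np.random.default_rng(7)
        pts = rng.normal(size=(12, 2))
        labels = ["a"] * 6 + ["b"] * 6
        from scipy.spatial.distance import pdist, squareform

        dm = as_distance_matrix(squareform(pdist(pts)),
                                [f"s{i}" for i in range(12)])
        design = GroupDesign.from_labels([f"s{i}" for i in range(12)], labels)
        dist, _ = group_centroid_distances(dm, design)
        expected = np.empty(12)
        for g in ("a", "b"):
            idx = [i for i, l in enumerate(labels) if l == g]
            centroid = pts[idx].mean(axis=0)
            expected[idx] = np.linalg.norm(pts[idx] - centroid, axis=1)
        np.testing.assert_allclose(dist.to_numpy(), expected, atol=1e-8)

    def test_semimetric_distances_stay_real(self, base_community):
        table, _ = base_community
        sub = CountTable(table.data.iloc[:20])
        dm = bray_curtis(sub)
        design = GroupDesign.from_labels(sub.sample_ids,
                                         ["a"] * 10 + ["b"] * 10)
        dist, means = group_centroid_distances(dm, design)
        assert np.isfinite(dist).all() and (dist >= 0).all()
        assert set(means) == {"a", "b"}

    def test_singleton_group_warns(self):
        dm = as_distance_matrix([[0, 1, 1], [1, 0, 1], [1, 1, 0]],
                                ["a", "b", "c"])
        design = GroupDesign({"a": "g1", "b": "g1", "c": "solo"})
        with pytest.warns(UserWarning, match="single member"):
            dist, _ = group_centroid_distances(dm, design)
        assert dist["c"] == 0.0
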