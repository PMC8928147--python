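import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from divpower.alpha import (
    alpha_table,
    alpha_summary,
    chao1,
    faith_pd,
    observed_richness,
    shannon,
    simpson,
)
from divpower.community import CountTable, ValidationError, read_tree
from divpower.simulate import random_tree

counts_strategy = st.lists(
    st.integers(min_value=0, max_value=40), min_size=2, max_size=30
).filter(lambda x: sum(x) > 0)


class TestObservedRichness:
    def test_counts_nonzeros(self):
        assert observed_richness([3, 0, 1, 7]) == 3

    def test_all_zero_is_zero(self):
        assert observed_richness([0, 0, 0]) == 0

    def test_negative_rejected(self):
        with pytest.raises(ValidationError):
            observed_richness([1, -1])

    @settings(derandomize=True)
    @given(st.lists(st.integers(0, 1), min_size=1, max_size=50))
    def test_binary_vector_equals_sum(self, bits):
        assert observed_richness(bits) == sum(bits)


class TestChao1:
    def test_no_singletons_returns_observed(self):
        counts = [5] * 10
        assert chao1(counts) == 10

    def test_formula_f1_2_f2_1(self):
        # s=5, F1=2, F2=1 -> 5 + 2*1/(2*2) = 5.5
        assert chao1([1, 1, 2, 3, 5]) == pytest.approx(5.5)

    def test_f2_zero_well_defined(self):
        # s=4, F1=3, F2=0 -> 4 + 3*2/2 = 7
        assert chao1([1, 1, 1, 5]) == pytest.approx(7.0)

    def test_non_integer_rejected(self):
        with pytest.raises(ValidationError, match="integer"):
            chao1([1.5, 2.0])

    @settings(derandomize=True)
    @given(counts_strategy)
    def test_never_below_observed(self, counts):
        f1 = counts.count(1)
        est = chao1(counts)
        obs = observed_richness(counts)
        assert est >= obs - 1e-12
        if f1 == 0:
            assert est == obs


class TestShannon:
    def test_two_even_taxa(self):
        assert shannon([1, 1]) == pytest.approx(math.log(2))

    def test_single_taxon_zero(self):
        assert shannon([0, 5, 0]) == 0.0

    @pytest.mark.parametrize("s", [2, 5, 17, 50])
    def test_even_community_closed_form(self, s):
        assert shannon([7] * s) == pytest.approx(math.log(s))

    def test_all_zero_rejected(self):
        with pytest.raises(ValidationError):
            shannon([0, 0])

    @settings(derandomize=True)
    @given(counts_strategy, st.floats(0.1, 100))
    def test_scale_invariance(self, counts, c):
        x = np.asarray(counts, dtype=float)
        assert shannon(x * c) == pytest.approx(shannon(x), abs=1e-9)

    @settings(derandomize=True)
    @given(counts_strategy)
    def test_merging_taxa_never_increases_entropy(self, counts):
        x = np.asarray(counts, dtype=float)
        merged = x.copy()
        merged[0] += merged[1]
        merged = np.delete(merged, 1)
        assert shannon(merged) <= shannon(x) + 1e-9


class TestSimpson:
    def test_two_even_taxa_gini(self):
        assert simpson([1, 1]) == pytest.approx(0.5)

    def test_single_taxon_forms(self):
        assert simpson([9]) == 0.0
        assert simpson([9], form="inverse") == pytest.approx(1.0)

    @settings(derandomize=True)
    @given(counts_strategy)
    def test_form_identities(self, counts):
        dom = simpson(counts, form="dominance")
        assert simpson(counts, form="inverse") == pytest.approx(1.0 / dom)
        assert simpson(counts, form="gini") == pytest.approx(1.0 - dom)

    @settings(derandomize=True)
    @given(counts_strategy)
    def test_gini_in_unit_interval(self, counts):
        assert 0.0 <= simpson(counts) <= 1.0

    @settings(derandomize=True)
    @given(counts_strategy)
    def test_merging_taxa_never_increases_gini(self, counts):
        x = np.asarray(counts, dtype=float)
        merged = x.copy()
        merged[0] += merged[1]
        merged = np.delete(merged, 1)
        assert simpson(merged) <= simpson(x) + 1e-9


def brute_force_pd(tree, present_leaves):
    """Union of leaf-to-root edge paths, summed by edge length."""
    edges = set()
    total = 0.0
    for tip in tree.tips():
        if tip.name not in present_leaves:
            continue
        node = tip
        while node is not None:
            edges.add(id(node))
            node = node.parent
    for node in tree.traverse(include_self=True):
        if id(node) in edges and node.length:
            total += node.length
    return total


class TestFaithPD:
    def test_star_tree_all_present(self):
        tree = read_tree("(A:1,B:2,C:3):0;")
        assert faith_pd([1, 1, 1], tree, ["A", "B", "C"]) == pytest.approx(6.0)

    def test_single_taxon_includes_root_path(self, three_leaf_tree):
        assert faith_pd([1, 0, 0], three_leaf_tree, ["A", "B", "C"]) == \
            pytest.approx(1.5)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_matches_brute_force_edge_union(self, seed):
        rng = np.random.default_rng(seed)
        n_leaves = int(rng.integers(4, 15))
        ids = [f"L{i}" for i in range(n_leaves)]
        tree = random_tree(ids, rng)
        for _ in range(5):
            presence = rng.random(n_leaves) < 0.5
            if not presence.any():
                presence[0] = True
            expected = brute_force_pd(tree, {i for i, keep
                                             in zip(ids, presence) if keep})
            got = faith_pd(presence.astype(float), tree, ids)
            assert got == pytest.approx(expected, abs=1e-10)

    def test_monotone_in_observed_set(self, three_leaf_tree):
        ids = ["A", "B", "C"]
        base = faith_pd([1, 0, 0], three_leaf_tree, ids)
        bigger = faith_pd([1, 1, 0], three_leaf_tree, ids)
        assert bigger >= base

    def test_skbio_agreement(self, base_community):
        from skbio.diversity.alpha import faith_pd as skbio_pd

        table, tree = base_community
        sub = table.values[:5]
        for row in sub:
            mine = faith_pd(row, tree, table.feature_ids)
            ref = skbio_pd(row.astype(int), taxa=table.feature_ids, tree=tree)
            assert mine == pytest.approx(ref, rel=1e-10)


class TestAlphaTable:
    def test_observed_column(self):
        t = CountTable(pd.DataFrame([[1, 1, 0], [0, 1, 1]],
                                    index=["a", "b"],
                                    columns=["x", "y", "z"]))
        out = alpha_table(t, ["observed"])
        assert out["observed"].tolist() == [2.0, 2.0]

    def test_identical_samples_zero_sd(self):
        t = CountTable(pd.DataFrame([[3, 1], [3, 1]], index=["a", "b"],
                                    columns=["x", "y"]))
        summary = alpha_summary(alpha_table(t, ["shannon", "simpson"]))
        assert (summary.loc["sd"] == 0).all()

    def test_matches_per_sample_loop(self, base_community):
        table, tree = base_community
        sub = CountTable(table.data.iloc[:50])
        out = alpha_table(sub, ["observed", "pd", "chao1", "shannon",
                                "simpson"], tree=tree)
        for i, row in enumerate(sub.values):
            assert out["observed"].iloc[i] == observed_richness(row)
            assert out["chao1"].iloc[i] == pytest.approx(chao1(row))
            assert out["shannon"].iloc[i] == pytest.approx(shannon(row))
            assert out["simpson"].iloc[i] == pytest.approx(simpson(row))
            assert out["pd"].iloc[i] == pytest.approx(
                faith_pd(row, tree, sub.feature_ids)
            )

    def test_pd_without_tree_rejected(self, tiny_table):
        with pytest.raises(ValidationError, match="tree"):
            alpha_table(tiny_table, ["pd"])

    def test_chao1_at_least_observed_on_synthetic(self, base_community):
        table, _ = base_community
        out = alpha_table(table, ["observed", "chao1"])
        assert (out["chao1"] >= out["observed"] - 1e-12).all()
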