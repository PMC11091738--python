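"""Entropy/gain-ratio values, the three family searches against hand-worked
examples, suggestions, partial completion, and brute-force oracle parity."""

import numpy as np
import pytest

import _oracle as oracle
from mixtree import (
    PairFilter,
    PartialTest,
    TSPTest,
    best_c45_split,
    best_tsp_split,
    best_wtsp_split,
    complete_partial_test,
    entropy,
    gain_ratio,
    suggest_top_splits,
)
from mixtree.errors import (
    DegenerateSplitError,
    InputError,
    NotApplicableError,
    StructuralError,
)
from mixtree.split_tests import CATEGORY, THRESHOLD

from conftest import make_dataset, random_dataset


class TestEntropyAndGainRatio:
    def test_entropy_values(self):
        assert entropy([8, 8]) == 1.0
        assert entropy([4, 0]) == 0.0
        # -(0.75*log2(0.75) + 0.25*log2(0.25)) = 0.811278...
        assert entropy([6, 2]) == pytest.approx(0.8112781244591328, abs=1e-12)
        assert entropy([1, 1, 1, 1]) == 2.0

    def test_entropy_of_empty_counts_is_an_error(self):
        with pytest.raises(InputError):
            entropy([0, 0])

    def test_perfect_balanced_split(self):
        assert gain_ratio([4, 4], [4, 0], [0, 4]) == (1.0, 1.0, 1.0)

    def test_six_two_split(self):
        gr, ig, si = gain_ratio([6, 2], [4, 0], [2, 2])
        assert gr == pytest.approx(0.3112781244591328, abs=1e-12)
        assert ig == pytest.approx(0.3112781244591328, abs=1e-12)
        assert si == 1.0

    def test_empty_side_is_degenerate(self):
        with pytest.raises(DegenerateSplitError):
            gain_ratio([5, 3], [5, 3], [0, 0])

    def test_matches_independent_formula_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            parent = rng.integers(1, 20, size=3)
            left = np.array([rng.integers(0, p + 1) for p in parent])
            right = parent - left
            if left.sum() == 0 or right.sum() == 0:
                continue
            got = gain_ratio(parent, left, right)
            st = oracle.stats(list(parent), list(left))
            assert got == pytest.approx(st, abs=1e-12)

    def test_invariant_under_class_and_row_permutation(self):
        gr1 = gain_ratio([6, 2], [4, 0], [2, 2])[0]
        gr2 = gain_ratio([2, 6], [0, 4], [2, 2])[0]
        assert gr1 == pytest.approx(gr2, abs=1e-12)


class TestC45Search:
    def test_optimal_threshold_on_separable_toy(self, threshold_toy):
        s = best_c45_split(threshold_toy, attribute="g1")
        assert s.test.mode == THRESHOLD
        assert s.test.threshold == 3.5  # midpoint between 2 and 5
        assert s.gain_ratio == 1.0

    def test_pure_node_has_no_split(self):
        ds = make_dataset({"g1": [1, 2, 3, 4]}, [0, 0, 0, 0], ("A",))
        assert best_c45_split(ds, attribute="g1") is None

    def test_constant_attribute_has_no_split(self, threshold_toy):
        assert best_c45_split(threshold_toy, attribute="g2") is None

    def test_nominal_category_enumeration(self, nominal_toy):
        s = best_c45_split(nominal_toy, attribute="color")
        assert s.test.mode == CATEGORY
        assert s.test.category == "red"
        assert s.gain_ratio == 1.0
        assert list(s.left_counts) == [2, 0]


class TestPairSearch:
    def test_tsp_toy_brute_forced(self, tsp_toy):
        s = best_tsp_split(tsp_toy)
        assert s.test == TSPTest("g1", "g2")
        assert s.gain_ratio == 1.0
        cands = oracle.tsp_candidates(
            *_cols_kinds(tsp_toy), list(tsp_toy.labels), 2
        )
        assert oracle.best(cands).describe == ("tsp", 0, 1)

    def test_pair_filter_fixes_first_attribute(self, tsp_toy):
        s = best_tsp_split(tsp_toy, pair_filter=PairFilter(attribute1="g3"))
        assert s.test.attribute1 == "g3"
        cands = [
            c
            for c in oracle.tsp_candidates(
                *_cols_kinds(tsp_toy), list(tsp_toy.labels), 2
            )
            if c.describe[1] == 2
        ]
        assert oracle.best(cands).describe[2] == {"g1": 0, "g2": 1, "g3": 2}[
            s.test.attribute2
        ]

    def test_single_continuous_attribute_not_applicable(self):
        ds = make_dataset({"g1": [1, 2, 3, 4]}, [0, 0, 1, 1])
        with pytest.raises(NotApplicableError):
            best_tsp_split(ds)

    def test_wtsp_ratio_midpoint_weight(self):
        # ratios 0.5, 0.8 (class A) vs 1.2, 2.0 (class B); denominators all 1
        ds = make_dataset(
            {"g1": [0.5, 0.8, 1.2, 2.0], "g2": [1.0, 1.0, 1.0, 1.0]},
            [0, 0, 1, 1],
        )
        s = best_wtsp_split(ds, pair_filter=PairFilter("g1", "g2"))
        assert s.test.weight == 1.0  # midpoint of 0.8 and 1.2
        assert s.gain_ratio == 1.0

    def test_zero_denominator_skips_pair_but_not_search(self):
        ds = make_dataset(
            {"g1": [1, 2, 5, 6], "g2": [0.0, 1, 1, 1], "g3": [2, 3, 1, 1]},
            [0, 0, 1, 1],
        )
        s = best_wtsp_split(ds)
        assert s is not None
        assert s.test.attribute2 != "g2"  # any pair dividing by g2 is skipped

    def test_fixed_weight_one_matches_tsp(self, tsp_toy):
        tsp = best_tsp_split(tsp_toy)
        wtsp = best_wtsp_split(tsp_toy, pair_filter=PairFilter(weight=1.0))
        assert (wtsp.test.attribute1, wtsp.test.attribute2) == (
            tsp.test.attribute1,
            tsp.test.attribute2,
        )
        assert wtsp.gain_ratio == pytest.approx(tsp.gain_ratio, abs=1e-12)


class TestSuggestions:
    def test_pure_node_yields_nothing(self):
        ds = make_dataset({"g1": [1, 2, 3, 4], "g2": [4, 3, 2, 1]}, [0] * 4, ("A",))
        assert suggest_top_splits(ds, k=3) == []

    def test_top_of_pool_is_perfect_on_toy(self, tsp_toy):
        top = suggest_top_splits(tsp_toy, k=3)
        assert len(top) == 3
        assert top[0].gain_ratio == 1.0
        assert [s.gain_ratio for s in top] == sorted(
            (s.gain_ratio for s in top), reverse=True
        )

    def test_k_is_a_prefix_property(self, tsp_toy):
        head1 = suggest_top_splits(tsp_toy, k=1)[0]
        head3 = suggest_top_splits(tsp_toy, k=3)[0]
        assert head1.test == head3.test
        assert head1.gain_ratio == head3.gain_ratio

    def test_no_duplicate_tests(self, tsp_toy):
        top = suggest_top_splits(tsp_toy, k=10)
        assert len({s.test for s in top}) == len(top)


class TestCompletion:
    def test_c45_attribute_fixed_finds_threshold(self, threshold_toy):
        s = complete_partial_test(
            threshold_toy, partial=PartialTest("c45", attribute="g1")
        )
        assert s.test.threshold == 3.5

    def test_tsp_partner_found_automatically(self, tsp_toy):
        s = complete_partial_test(
            tsp_toy, partial=PartialTest("tsp", attribute1="g1")
        )
        assert s.test.attribute2 == "g2"

    def test_wtsp_both_attributes_fixed_searches_weight_only(self, tsp_toy):
        s = complete_partial_test(
            tsp_toy, partial=PartialTest("wtsp", attribute1="g3", attribute2="g2")
        )
        assert (s.test.attribute1, s.test.attribute2) == ("g3", "g2")

    def test_equal_attributes_violate_invariants(self):
        with pytest.raises(StructuralError):
            PartialTest("wtsp", attribute1="g1", attribute2="g1")


def _cols_kinds(ds):
    columns, kinds, _ = oracle.dataset_columns(ds)
    return columns, kinds


class TestOracleParity:
    """The exhaustive searches equal an independent brute-force enumeration
    (the full 200-dataset sweep runs in the acceptance suite)."""

    @pytest.mark.parametrize("seed", range(20))
    def test_quick_parity(self, seed):
        ds = random_dataset(1000 + seed)
        columns, kinds, categories = oracle.dataset_columns(ds)
        labels = list(ds.labels)
        C = ds.n_classes

        pairs = [
            (best_c45_split(ds), oracle.c45_candidates(columns, kinds, categories, labels, C)),
            (best_tsp_split(ds), oracle.tsp_candidates(columns, kinds, labels, C)),
            (best_wtsp_split(ds), oracle.wtsp_candidates(columns, kinds, labels, C)),
        ]
        for got, cands in pairs:
            want = oracle.best(cands)
            if want is None:
                assert got is None
            else:
                assert oracle.describe_test(got.test, ds) == want.describe
                assert got.gain_ratio == pytest.approx(want.gr, abs=1e-9)

    @pytest.mark.parametrize("seed", range(5))
    def test_returned_split_invariants(self, seed):
        ds = random_dataset(2000 + seed)
        for s in suggest_top_splits(ds, k=20):
            assert s.info_gain > 0
            assert s.split_info > 0
            assert np.array_equal(
                s.left_counts + s.right_counts, ds.class_counts()
            )
            assert s.gain_ratio == pytest.approx(
                s.info_gain / s.split_info, abs=1e-12
            )

    def test_sklearn_stump_agrees_on_unambiguous_axis_split(self):
        """Independent cross-check: where the optimal univariate split is
        unambiguous, an entropy-criterion decision stump from scikit-learn
        chooses the same attribute and the same midpoint threshold."""
        from sklearn.tree import DecisionTreeClassifier

        ds = random_dataset(4242, allow_nominal=False)
        X = ds.continuous_matrix([a.name for a in ds.attributes])
        stump = DecisionTreeClassifier(criterion="entropy", max_depth=1,
                                       random_state=0).fit(X, ds.labels)
        ours = best_c45_split(ds)
        assert ours.test.attribute == ds.attributes[
            stump.tree_.feature[0]
        ].name
        assert ours.test.threshold == pytest.approx(
            stump.tree_.threshold[0], rel=1e-9
        )

    def test_row_permutation_invariance(self):
        ds = random_dataset(42)
        rows = np.arange(ds.n_samples)
        rng = np.random.default_rng(0)
        perm = rng.permutation(rows)
        a = best_tsp_split(ds, rows)
        b = best_tsp_split(ds, perm)
        assert a.test == b.test
        assert a.gain_ratio == pytest.approx(b.gain_ratio, abs=1e-12)
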