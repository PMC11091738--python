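"""Interactive edit semantics: fold, unfold, update, rebuild — all pure,
all with statistics recomputed from scratch."""

import numpy as np
import pytest

from mixtree import (
    C45Test,
    InductionConfig,
    PairRule,
    PlantedRuleSpec,
    ThresholdRule,
    evaluate,
    export_tree,
    fold,
    generate,
    induce,
    rebuild_subtree,
    unfold_all,
    unfold_once,
    update_test,
)
from mixtree.errors import NotApplicableError, StructuralError
from mixtree.induction import grow_subtree, majority_class
from mixtree.split_tests import THRESHOLD

from conftest import make_dataset


def _cfg(**kw):
    kw.setdefault("min_node_size", 1)
    return InductionConfig(**kw)


@pytest.fixture
def noisy_ds():
    return generate(
        PlantedRuleSpec(ThresholdRule(0, 1.0), n_samples=80, n_attributes=5,
                        noise_rate=0.15, seed=11)
    )


@pytest.fixture
def depth1():
    """Depth-1 tree: root test g1 >= 3.5 on a 4-row fixture."""
    ds = make_dataset({"g1": [1, 2, 5, 6], "g2": [9, 9, 9, 9]}, [0, 0, 1, 1])
    return ds, induce(ds, _cfg(max_depth=1))


class TestFold:
    def test_fold_root_gives_global_majority_leaf(self, noisy_ds):
        tree = induce(noisy_ds, _cfg())
        res = fold(tree, "root", noisy_ds)
        assert res.tree.root.is_leaf
        maj = majority_class(noisy_ds.class_counts())
        assert res.tree.root.predicted_class == maj
        assert res.train_report.accuracy == pytest.approx(
            noisy_ds.class_counts().max() / noisy_ds.n_samples
        )

    def test_fold_a_leaf_is_a_no_op(self, noisy_ds):
        tree = induce(noisy_ds, _cfg(entropy_threshold=2.0))
        assert tree.root.is_leaf
        res = fold(tree, "root", noisy_ds)
        assert export_tree(res.tree) == export_tree(tree)

    def test_fold_reports_match_from_scratch_evaluation(self, noisy_ds):
        tree = induce(noisy_ds, _cfg())
        res = fold(tree, "L", noisy_ds)
        fresh = evaluate(res.tree, noisy_ds)
        assert res.train_report.to_dict() == fresh.to_dict()

    def test_fold_does_not_mutate_input(self, noisy_ds):
        tree = induce(noisy_ds, _cfg())
        before = export_tree(tree)
        fold(tree, "root", noisy_ds)
        assert export_tree(tree) == before


class TestUnfold:
    def test_unfold_once_on_pure_leaf_not_applicable(self):
        ds = make_dataset({"g1": [1, 2, 3, 4], "g2": [4, 3, 2, 1]}, [0] * 4, ("A",))
        tree = induce(ds, _cfg())
        with pytest.raises(NotApplicableError):
            unfold_once(tree, "root", ds)

    def test_unfold_once_with_family_override_finds_planted_pair(self):
        ds = generate(PlantedRuleSpec(PairRule(0, 1), n_samples=50,
                                      n_attributes=5, seed=7))
        tree = induce(ds, _cfg(entropy_threshold=2.0))  # start from one leaf
        res = unfold_once(tree, "root", ds, family_override=("tsp",))
        root = res.tree.root
        assert (root.test.attribute1, root.test.attribute2) == ("g0", "g1")
        assert root.left.is_leaf and root.right.is_leaf
        assert root.left.depth == root.depth + 1
        assert res.train_report.accuracy == 1.0

    def test_unfold_all_at_root_of_leaf_tree_equals_induce(self, noisy_ds):
        cfg = _cfg(families=("c45", "tsp"))
        stub = induce(noisy_ds, _cfg(entropy_threshold=2.0))
        res = unfold_all(stub, "root", noisy_ds, config=cfg)
        direct = induce(noisy_ds, cfg)
        direct_res_tree = export_tree(direct)
        got = export_tree(res.tree)
        # configs differ (stub carries its own), compare structure via root doc
        import json

        assert json.loads(got)["root"] == json.loads(direct_res_tree)["root"]

    def test_fold_then_unfold_all_restores_subtree(self, noisy_ds):
        cfg = _cfg()
        tree = induce(noisy_ds, cfg)
        assert not tree.root.left.is_leaf or not tree.root.right.is_leaf
        path = "L" if not tree.root.left.is_leaf else "R"
        folded = fold(tree, path, noisy_ds)
        restored = unfold_all(folded.tree, path, noisy_ds, config=cfg)
        assert export_tree(restored.tree) == export_tree(tree)

    def test_unfold_all_respects_tree_wide_node_budget(self, noisy_ds):
        cfg = InductionConfig(min_node_size=1, max_nodes=3)
        tree = induce(noisy_ds, cfg)
        leaf_paths = [
            n.id for n in tree.nodes() if n.is_leaf and n.id != "root"
        ]
        path = leaf_paths[0].replace("root", "")
        res = unfold_all(tree, path, noisy_ds, config=cfg)
        assert res.tree.n_internal() <= 3


class TestUpdate:
    def test_identity_update_changes_nothing(self, depth1):
        ds, tree = depth1
        res = update_test(tree, "root", tree.root.test, ds)
        assert export_tree(res.tree) == export_tree(tree)
        assert res.train_report.to_dict() == evaluate(tree, ds).to_dict()

    def test_unreachable_threshold_empties_left_leaf(self, depth1):
        ds, tree = depth1
        res = update_test(
            tree, "root", C45Test("g1", THRESHOLD, threshold=10.0), ds
        )
        root = res.tree.root
        assert root.left.train_counts.sum() == 0
        assert root.right.train_counts.sum() == 4
        # empty leaf falls back to the nearest ancestor's majority (tie -> A)
        assert root.left.predicted_class == 0

    def test_counts_match_full_reevaluation(self, noisy_ds):
        tree = induce(noisy_ds, _cfg())
        res = update_test(
            tree, "root", C45Test("g2", THRESHOLD, threshold=1.0), noisy_ds
        )
        fresh = evaluate(res.tree, noisy_ds)
        assert res.train_report.to_dict() == fresh.to_dict()
        for node in res.tree.nodes():
            assert list(map(int, node.train_counts)) == fresh.node_counts[node.id]

    def test_update_preserves_descendant_structure(self, noisy_ds):
        import json

        tree = induce(noisy_ds, _cfg())
        res = update_test(
            tree, "root", C45Test("g3", THRESHOLD, threshold=0.5), noisy_ds
        )

        def shape(obj):
            if obj["kind"] == "leaf":
                return "leaf"
            return (obj["test"]["repr"], shape(obj["left"]), shape(obj["right"]))

        old = json.loads(export_tree(tree))["root"]
        new = json.loads(export_tree(res.tree))["root"]
        assert shape(old["left"]) == shape(new["left"])
        assert shape(old["right"]) == shape(new["right"])


class TestRebuild:
    def test_rebuild_root_equals_fresh_induction(self, noisy_ds):
        cfg = _cfg(families=("c45",))
        tree = induce(noisy_ds, cfg)
        res = rebuild_subtree(tree, "root", noisy_ds)
        assert export_tree(res.tree) == export_tree(tree)

    def test_rebuild_with_bad_test_grows_valid_greedy_children(self, noisy_ds):
        cfg = _cfg()
        tree = induce(noisy_ds, cfg)
        bad = C45Test("g4", THRESHOLD, threshold=0.9)
        res = rebuild_subtree(tree, "root", noisy_ds, new_test=bad, config=cfg)
        root = res.tree.root
        assert root.test == bad
        from mixtree.split_tests import route_mask

        mask = route_mask(bad, noisy_ds)
        rows = np.arange(noisy_ds.n_samples)
        for child, sub_rows in ((root.left, rows[mask]), (root.right, rows[~mask])):
            oracle = grow_subtree(noisy_ds, sub_rows, 1, cfg, nodes_used=1)
            assert _shape(child) == _shape(oracle)

    def test_rebuild_differs_from_update_below_children(self, noisy_ds):
        tree = induce(noisy_ds, _cfg())
        new = C45Test("g2", THRESHOLD, threshold=1.0)
        up = update_test(tree, "root", new, noisy_ds)
        rb = rebuild_subtree(tree, "root", noisy_ds, new_test=new)
        assert up.tree.root.test == rb.tree.root.test == new
        assert export_tree(up.tree) != export_tree(rb.tree)

    def test_unresolvable_path_is_structural_error(self, noisy_ds):
        tree = induce(noisy_ds, _cfg(max_depth=1))
        with pytest.raises(StructuralError):
            rebuild_subtree(tree, "LLLLLL", noisy_ds)


def _shape(node):
    if node.is_leaf:
        return ("leaf", node.predicted_class, tuple(node.train_counts))
    return (node.test, _shape(node.left), _shape(node.right))
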