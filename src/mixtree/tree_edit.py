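"""Interactive editing semantics as pure, deterministic tree transformations.

Every operation takes a tree plus the training (and optional test) data and
returns an :class:`EditResult` holding a NEW tree together with freshly
recomputed train/test reports — edits never mutate their input and never
leave stale statistics.  Test-set rows are routed and reported but never
influence structure, labels, or split choice.

Operations mirror the interactive vocabulary of tree editors:

* ``fold`` — collapse an internal node's subtree into a leaf (manual pruning);
* ``unfold_once`` — expand a leaf by the single best split (optionally with
  a different family set than the tree was built with);
* ``unfold_all`` — expand a leaf by full recursive induction, with the
  node budget counted tree-wide;
* ``update_test`` — replace a node's test, keep the descendant structure,
  re-route the instances and refresh every descendant's counts and labels;
* ``rebuild_subtree`` — replace (or re-search) a node's test and re-induce
  both children from scratch.

Nodes are addressed by their root-to-node path of left/right steps
(e.g. ``"L.R.L"``), which is stable under serialisation.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, replace as dc_replace

import numpy as np

from .dataset import Dataset
from .errors import NotApplicableError, StructuralError
from .evaluation import EvaluationReport, evaluate
from .induction import (
    LEAF,
    INTERNAL,
    InductionConfig,
    Tree,
    TreeNode,
    assign_ids,
    grow_subtree,
    majority_class,
)
from .split_search import search_best_split
from .split_tests import SplitTest, route_mask, validate_test

NodePath = tuple[str, ...]  # sequence of "L" / "R" steps from the root


def parse_path(text: str) -> NodePath:
    """Parse ``"L.R.L"`` (dots optional; case-insensitive; ``""`` or
    ``"root"`` is the root) into a path tuple."""
    text = text.strip()
    if text.lower() in ("", "root"):
        return ()
    steps = []
    for ch in text.replace(".", "").upper():
        if ch not in ("L", "R"):
            raise StructuralError(f"invalid node path {text!r}")
        steps.append(ch)
    return tuple(steps)


def format_path(path: NodePath) -> str:
    return ".".join(path) if path else "root"


def resolve(tree: Tree, path) -> TreeNode:
    """Resolve a path (tuple or text) to a node; StructuralError if absent."""
    if isinstance(path, str):
        path = parse_path(path)
    node = tree.root
    for step in path:
        if node.is_leaf:
            raise StructuralError(f"path {format_path(tuple(path))!r} leaves the tree")
        node = node.left if step == "L" else node.right
    return node


@dataclass
class EditResult:
    """Outcome of one edit: the new tree plus from-scratch reports."""

    tree: Tree
    changed_node: NodePath
    train_report: EvaluationReport
    test_report: EvaluationReport | None = None


def refresh_training_state(tree: Tree, train: Dataset) -> None:
    """Re-route the training set from the root; refresh every node's rows
    and counts and every leaf's predicted class (majority of its rows; a
    leaf reached by no row predicts its nearest ancestor's majority)."""

    def visit(node: TreeNode, rows: np.ndarray, fallback: int) -> None:
        node.rows = rows
        node.train_counts = train.class_counts(rows)
        maj = majority_class(node.train_counts) if len(rows) else fallback
        if node.is_leaf:
            node.predicted_class = maj
            return
        node.predicted_class = None
        mask = route_mask(node.test, train, rows)
        visit(node.left, rows[mask], maj)
        visit(node.right, rows[~mask], maj)

    all_rows = np.arange(train.n_samples)
    root_major = majority_class(train.class_counts(all_rows))
    visit(tree.root, all_rows, root_major)


def _finalize(
    tree: Tree, path: NodePath, train: Dataset, test: Dataset | None
) -> EditResult:
    refresh_training_state(tree, train)
    assign_ids(tree)
    return EditResult(
        tree=tree,
        changed_node=path,
        train_report=evaluate(tree, train),
        test_report=evaluate(tree, test) if test is not None else None,
    )


def _copy_and_resolve(tree: Tree, path) -> tuple[Tree, TreeNode, NodePath]:
    if isinstance(path, str):
        path = parse_path(path)
    resolve(tree, path)  # fail before copying
    new = copy.deepcopy(tree)
    return new, resolve(new, path), tuple(path)


def _internal_count_outside(tree: Tree, node: TreeNode) -> int:
    inside = sum(1 for n in node.walk() if not n.is_leaf)
    return tree.n_internal() - inside


def fold(
    tree: Tree, path, train: Dataset, test: Dataset | None = None
) -> EditResult:
    """Collapse the subtree at ``path`` into a leaf labelled with the
    majority class of the training rows reaching it.  Folding a leaf is a
    no-op (the tree is returned unchanged, statistics still refreshed)."""
    new, node, path = _copy_and_resolve(tree, path)
    if not node.is_leaf:
        node.kind = LEAF
        node.test = None
        node.left = None
        node.right = None
        node.predicted_class = majority_class(node.train_counts)
    return _finalize(new, path, train, test)


def unfold_once(
    tree: Tree,
    path,
    train: Dataset,
    test: Dataset | None = None,
    family_override=None,
    config: InductionConfig | None = None,
) -> EditResult:
    """Expand the leaf at ``path`` into one internal node with two leaf
    children, using the best split over ``family_override`` (defaults to the
    tree's configured families).  No recursion."""
    config = config or tree.config
    families = tuple(family_override) if family_override else config.families
    new, node, path = _copy_and_resolve(tree, path)
    if not node.is_leaf:
        raise StructuralError(f"node {format_path(path)!r} is not a leaf")
    refresh_training_state(new, train)  # make sure node.rows is current
    node = resolve(new, path)
    split = search_best_split(
        train,
        node.rows,
        families,
        min_child_size=config.min_node_size,
        max_pairs=config.max_pairs,
    )
    if split is None:
        raise NotApplicableError(
            f"no legal split at node {format_path(path)!r}"
        )
    node.kind = INTERNAL
    node.test = split.test
    node.predicted_class = None
    for side in ("L", "R"):
        child = TreeNode(
            id=node.id + side,
            kind=LEAF,
            depth=node.depth + 1,
            train_counts=np.zeros(len(new.class_levels), dtype=np.int64),
        )
        if side == "L":
            node.left = child
        else:
            node.right = child
    return _finalize(new, path, train, test)


def unfold_all(
    tree: Tree,
    path,
    train: Dataset,
    test: Dataset | None = None,
    family_override=None,
    config: InductionConfig | None = None,
) -> EditResult:
    """Expand the leaf at ``path`` by full recursive induction on the rows
    reaching it; depth and internal-node budgets are counted from the
    existing tree."""
    config = config or tree.config
    if family_override:
        config = dc_replace(config, families=tuple(family_override))
    new, node, path = _copy_and_resolve(tree, path)
    if not node.is_leaf:
        raise StructuralError(f"node {format_path(path)!r} is not a leaf")
    refresh_training_state(new, train)
    node = resolve(new, path)
    used = _internal_count_outside(new, node)
    subtree = grow_subtree(
        train, node.rows, node.depth, config, nodes_used=used, path="".join(path)
    )
    _replace_node(new, path, subtree)
    return _finalize(new, path, train, test)


def update_test(
    tree: Tree,
    path,
    new_test: SplitTest,
    train: Dataset,
    test: Dataset | None = None,
) -> EditResult:
    """Replace the test at an internal node, preserving all descendant
    structure; instances are re-routed from the edited node downward and
    every descendant's counts and leaf labels are refreshed."""
    validate_test(new_test, train)
    new, node, path = _copy_and_resolve(tree, path)
    if node.is_leaf:
        raise StructuralError(
            f"node {format_path(path)!r} is a leaf; use unfold instead"
        )
    node.test = new_test
    return _finalize(new, path, train, test)


def rebuild_subtree(
    tree: Tree,
    path,
    train: Dataset,
    test: Dataset | None = None,
    new_test: SplitTest | None = None,
    config: InductionConfig | None = None,
) -> EditResult:
    """Re-induce the subtree below ``path``.

    With ``new_test`` supplied, it is installed at the node and BOTH
    children are re-induced from scratch on the re-routed rows; without it,
    the whole subtree (the node included) is re-induced under ``config``
    (defaults to the tree's config) — at the root this is identical to
    fresh induction.
    """
    config = config or tree.config
    if new_test is not None:
        validate_test(new_test, train)
    new, node, path = _copy_and_resolve(tree, path)
    if node.is_leaf and new_test is None:
        raise StructuralError(
            f"rebuild at leaf {format_path(path)!r} requires a test; "
            "use unfold_all to grow it automatically"
        )
    refresh_training_state(new, train)
    node = resolve(new, path)
    used = _internal_count_outside(new, node)
    prefix = "".join(path)
    if new_test is None:
        subtree = grow_subtree(
            train, node.rows, node.depth, config, nodes_used=used, path=prefix
        )
        _replace_node(new, path, subtree)
    else:
        mask = route_mask(new_test, train, node.rows)
        left = grow_subtree(
            train, node.rows[mask], node.depth + 1, config,
            nodes_used=used + 1, path=prefix + "L",
        )
        used_after_left = used + 1 + sum(1 for n in left.walk() if not n.is_leaf)
        right = grow_subtree(
            train, node.rows[~mask], node.depth + 1, config,
            nodes_used=used_after_left, path=prefix + "R",
        )
        node.kind = INTERNAL
        node.test = new_test
        node.predicted_class = None
        node.left = left
        node.right = right
    return _finalize(new, path, train, test)


def _replace_node(tree: Tree, path: NodePath, subtree: TreeNode) -> None:
    if not path:
        tree.root = subtree
        return
    parent = resolve(tree, path[:-1])
    if path[-1] == "L":
        parent.left = subtree
    else:
        parent.right = subtree
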