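"""Route datasets through a tree and report its statistics.

The report carries overall accuracy, the confusion matrix (rows = actual,
columns = predicted, class order = the dataset's class-level order), the
set of samples reaching every node, and each leaf's local accuracy (the
fraction of its samples whose actual class equals the leaf's predicted
class).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dataset import Dataset
from .errors import InputError, StructuralError
from .induction import Tree, TreeNode
from .split_tests import route, route_mask


@dataclass
class EvaluationReport:
    n: int
    accuracy: float
    confusion: np.ndarray  # (C, C), rows = actual, columns = predicted
    class_levels: list[str]
    node_assignments: dict[str, list[str]]  # node id -> sorted sample ids
    node_counts: dict[str, list[int]]  # node id -> class counts of reaching rows
    leaf_accuracy: dict[str, float]

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "accuracy": self.accuracy,
            "class_levels": list(self.class_levels),
            "confusion": self.confusion.tolist(),
            "node_assignments": {k: list(v) for k, v in self.node_assignments.items()},
            "node_counts": {k: list(map(int, v)) for k, v in self.node_counts.items()},
            "leaf_accuracy": dict(self.leaf_accuracy),
        }


def _check_schema(tree: Tree, data: Dataset) -> None:
    names = {a.name for a in data.attributes}
    for a in tree.attributes:
        if a.name not in names:
            raise StructuralError(
                f"dataset lacks attribute {a.name!r} required by the tree"
            )
    for i, lvl in enumerate(tree.class_levels):
        if i >= len(data.class_levels) or data.class_levels[i] != lvl:
            raise StructuralError(
                "dataset class levels must start with the tree's class levels "
                f"(tree: {tree.class_levels}, data: {data.class_levels})"
            )


def predict(tree: Tree, instance) -> str:
    """Predicted class label for one instance (a mapping attribute -> value)."""
    node = tree.root
    while not node.is_leaf:
        node = node.left if route(node.test, instance) == "left" else node.right
    return tree.class_levels[node.predicted_class]


def predict_rows(tree: Tree, data: Dataset, rows=None) -> np.ndarray:
    """Vectorised prediction: class-level indices for the given rows."""
    rows = np.arange(data.n_samples) if rows is None else np.asarray(rows, np.int64)
    out = np.empty(len(rows), dtype=np.int64)

    def visit(node: TreeNode, idx: np.ndarray) -> None:
        if len(idx) == 0 and node.is_leaf:
            return
        if node.is_leaf:
            out[idx] = node.predicted_class
            return
        mask = route_mask(node.test, data, rows[idx])
        visit(node.left, idx[mask])
        visit(node.right, idx[~mask])

    visit(tree.root, np.arange(len(rows)))
    return out


def evaluate(tree: Tree, data: Dataset) -> EvaluationReport:
    """Route every row of ``data`` through the tree and assemble the report."""
    if data.n_samples == 0:
        raise InputError("cannot evaluate on an empty dataset")
    _check_schema(tree, data)
    n = data.n_samples
    C = len(data.class_levels)
    assignments: dict[str, list[str]] = {}
    node_counts: dict[str, list[int]] = {}
    leaf_acc: dict[str, float] = {}
    predicted = np.empty(n, dtype=np.int64)

    def visit(node: TreeNode, rows: np.ndarray) -> None:
        ids = sorted(data.sample_ids[i] for i in rows)
        assignments[node.id] = ids
        node_counts[node.id] = list(
            map(int, np.bincount(data.labels[rows], minlength=C))
        )
        if node.is_leaf:
            predicted[rows] = node.predicted_class
            if len(rows):
                leaf_acc[node.id] = float(
                    (data.labels[rows] == node.predicted_class).mean()
                )
            else:
                leaf_acc[node.id] = 0.0
            return
        mask = route_mask(node.test, data, rows)
        visit(node.left, rows[mask])
        visit(node.right, rows[~mask])

    visit(tree.root, np.arange(n))
    confusion = np.zeros((C, C), dtype=np.int64)
    np.add.at(confusion, (data.labels, predicted), 1)
    accuracy = float(np.trace(confusion) / n)
    return EvaluationReport(
        n=n,
        accuracy=accuracy,
        confusion=confusion,
        class_levels=list(data.class_levels),
        node_assignments=assignments,
        node_counts=node_counts,
        leaf_accuracy=leaf_acc,
    )
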