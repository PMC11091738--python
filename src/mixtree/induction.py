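"""Top-down greedy induction of binary mixed classification trees.

Starting from the root, the best split across the enabled test families is
installed (gain-ratio criterion, canonical tie-break) and the training rows
are redirected to the two subnodes; the process repeats until a stopping
rule fires.  No post-pruning is applied — pruning is a manual edit (fold).

A node becomes a leaf when the FIRST of these rules fires (fixed order):

``min_size``   node holds fewer than 2 * min_node_size rows, so no split
               could give both children at least min_node_size rows;
``max_depth``  the node sits at the depth limit;
``entropy``    the node's class entropy is at or below entropy_threshold;
``budget``     the internal-node budget ``max_nodes`` is exhausted
               (breadth-first creation order — remaining frontier nodes
               become leaves);
``no_split``   no candidate split has positive information gain with both
               children >= min_node_size.

"Maximum tree size" is deliberately available in both readings: as a depth
cap (``max_depth``) and as an internal-node count cap (``max_nodes``);
either can be used alone by leaving the other large.
"""

from __future__ import annotations

import math
from collections import deque
from dataclasses import dataclass, field, replace

import numpy as np

from .dataset import AttributeMeta, Dataset
from .errors import InputError, NotApplicableError
from .split_search import ScoredSplit, search_best_split
from .split_tests import FAMILIES, FAMILY_C45, SplitTest, route_mask

INTERNAL = "internal"
LEAF = "leaf"

STOP_MIN_SIZE = "min_size"
STOP_MAX_DEPTH = "max_depth"
STOP_ENTROPY = "entropy"
STOP_BUDGET = "budget"
STOP_NO_SPLIT = "no_split"
STOP_NONE = "none"


@dataclass(frozen=True)
class InductionConfig:
    """Induction parameters.

    families
        Enabled test families, subset of {"c45", "tsp", "wtsp"}.
    min_node_size
        Minimum number of training rows in each child of every split.
    max_depth, max_nodes
        Structural budgets: maximum leaf depth and maximum number of
        internal nodes.
    entropy_threshold
        A node whose class entropy (bits) is at or below this value is not
        split further (0 means: grow until pure).
    suggestion_k
        How many alternative splits to surface per node.
    max_pairs
        Optional cap on the number of ordered pairs scanned by TSP/WTSP
        (variance-ranked attribute prefilter); None scans all pairs.
    """

    families: tuple[str, ...] = (FAMILY_C45,)
    min_node_size: int = 5
    max_depth: int = 10
    max_nodes: int = 50
    entropy_threshold: float = 0.0
    suggestion_k: int = 5
    max_pairs: int | None = None

    def __post_init__(self) -> None:
        fams = tuple(f for f in FAMILIES if f in self.families)
        if not fams or set(self.families) - set(FAMILIES):
            raise InputError(
                f"families must be a non-empty subset of {FAMILIES}, got "
                f"{self.families!r}"
            )
        object.__setattr__(self, "families", fams)
        for name in ("min_node_size", "max_depth", "max_nodes", "suggestion_k"):
            if getattr(self, name) < 1:
                raise InputError(f"{name} must be a positive integer")
        if self.entropy_threshold < 0:
            raise InputError("entropy_threshold must be non-negative")


@dataclass
class TreeNode:
    """One tree node; internal nodes carry a test and two children, leaves a
    predicted class.  ``rows`` holds the training-row indices that reached
    the node (bookkeeping; refreshed by evaluation/edits)."""

    id: str
    kind: str
    depth: int
    train_counts: np.ndarray
    test: SplitTest | None = None
    left: "TreeNode | None" = None
    right: "TreeNode | None" = None
    predicted_class: int | None = None
    rows: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))

    @property
    def is_leaf(self) -> bool:
        return self.kind == LEAF

    def walk(self):
        yield self
        if not self.is_leaf:
            yield from self.left.walk()
            yield from self.right.walk()


@dataclass
class Tree:
    """An induced (or imported, or edited) classification tree."""

    root: TreeNode
    config: InductionConfig
    attributes: list[AttributeMeta]
    class_levels: list[str]

    def nodes(self):
        return self.root.walk()

    def n_internal(self) -> int:
        return sum(1 for n in self.nodes() if not n.is_leaf)

    def node_at(self, path) -> TreeNode:
        from .tree_edit import resolve  # local import to avoid a cycle

        return resolve(self, path)


def majority_class(counts: np.ndarray) -> int:
    """Majority class index; ties resolve to the lowest class index."""
    return int(np.argmax(counts))


def _node_entropy(counts: np.ndarray) -> float:
    n = counts.sum()
    if n == 0:
        return 0.0
    p = counts[counts > 0] / n
    return float(-(p * np.log2(p)).sum())


def stopping_reason(
    data: Dataset,
    rows,
    depth: int,
    config: InductionConfig,
    nodes_used: int = 0,
) -> str:
    """Which stopping rule (if any) makes this node a leaf.

    Rules are checked in the fixed order min_size, max_depth, entropy,
    budget, no_split; ``"none"`` means the node will split.
    """
    reason, _ = _decide(data, rows, depth, config, nodes_used)
    return reason


def _decide(data, rows, depth, config, nodes_used):
    rows = np.asarray(rows, dtype=np.int64) if rows is not None else np.arange(data.n_samples)
    counts = data.class_counts(rows)
    if len(rows) < 2 * config.min_node_size:
        return STOP_MIN_SIZE, None
    if depth >= config.max_depth:
        return STOP_MAX_DEPTH, None
    if _node_entropy(counts) <= config.entropy_threshold:
        return STOP_ENTROPY, None
    if nodes_used >= config.max_nodes:
        return STOP_BUDGET, None
    split = search_best_split(
        data,
        rows,
        config.families,
        min_child_size=config.min_node_size,
        max_pairs=config.max_pairs,
    )
    if split is None:
        return STOP_NO_SPLIT, None
    return STOP_NONE, split


def _check_applicable(data: Dataset, config: InductionConfig) -> None:
    from .dataset import CONTINUOUS

    has_any = bool(data.active_attributes())
    if not has_any:
        raise NotApplicableError("no non-ignored attributes to split on")
    if FAMILY_C45 not in config.families:
        if len(data.active_attributes(CONTINUOUS)) < 2:
            raise NotApplicableError(
                "pair-test families need at least two continuous attributes"
            )


def induce(data: Dataset, config: InductionConfig | None = None) -> Tree:
    """Build a tree from a training dataset.

    Fully deterministic: identical data and config yield an identical tree
    (node ids included — ids encode the root-to-node path, e.g. ``"LRL"``).
    """
    if config is None:
        config = InductionConfig()
    if data.n_samples == 0:
        raise InputError("cannot induce a tree from an empty dataset")
    _check_applicable(data, config)
    root = grow_subtree(data, np.arange(data.n_samples), 0, config, nodes_used=0)
    return Tree(root, config, list(data.attributes), list(data.class_levels))


def grow_subtree(
    data: Dataset,
    rows: np.ndarray,
    depth: int,
    config: InductionConfig,
    nodes_used: int,
    path: str = "",
) -> TreeNode:
    """Breadth-first greedy growth of a subtree over ``rows`` rooted at
    ``depth``; ``nodes_used`` internal nodes already exist elsewhere in the
    tree and count against ``max_nodes``."""
    rows = np.asarray(rows, dtype=np.int64)
    root = TreeNode(
        id=path or "root",
        kind=LEAF,
        depth=depth,
        train_counts=data.class_counts(rows),
        rows=rows,
    )
    root.predicted_class = majority_class(root.train_counts)
    used = nodes_used
    queue: deque[tuple[TreeNode, str]] = deque([(root, path)])
    while queue:
        node, npath = queue.popleft()
        reason, split = _decide(data, node.rows, node.depth, config, used)
        if reason != STOP_NONE:
            continue
        used += 1
        mask = route_mask(split.test, data, node.rows)
        left_rows = node.rows[mask]
        right_rows = node.rows[~mask]
        node.kind = INTERNAL
        node.test = split.test
        node.predicted_class = None
        for side, srows in (("L", left_rows), ("R", right_rows)):
            child = TreeNode(
                id=(npath + side) or side,
                kind=LEAF,
                depth=node.depth + 1,
                train_counts=data.class_counts(srows),
                rows=srows,
            )
            child.predicted_class = majority_class(child.train_counts)
            if side == "L":
                node.left = child
            else:
                node.right = child
            queue.append((child, npath + side))
    return root


def assign_ids(tree: Tree) -> None:
    """(Re)derive node ids from structure: the root is ``"root"``, children
    append ``L``/``R`` to the parent's path."""

    def visit(node: TreeNode, path: str) -> None:
        node.id = path or "root"
        if not node.is_leaf:
            visit(node.left, path + "L")
            visit(node.right, path + "R")

    visit(tree.root, "")
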