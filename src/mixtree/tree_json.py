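"""Lossless JSON interchange for trees.

The document layout is defined by ``tree.schema.json`` (shipped with the
package).  Serialisation is canonical — fixed key order, two-space indent,
shortest round-trip decimal floats — so exporting the same tree twice is
byte-identical, and export -> import -> export is a fixed point.

Routing convention recorded in the header: instances satisfying a node's
test always go to ``left``.  Stored class counts are validated on import
(children must sum to the parent) — a corrupted model must not load
silently.
"""

from __future__ import annotations

import json
from importlib import resources

import numpy as np

from .dataset import CONTINUOUS, NOMINAL, AttributeMeta, Dataset
from .errors import FormatError, ResolutionError, VersionError
from .induction import INTERNAL, LEAF, InductionConfig, Tree, TreeNode, assign_ids
from .split_tests import (
    CATEGORY,
    FAMILY_C45,
    FAMILY_TSP,
    FAMILY_WTSP,
    THRESHOLD,
    C45Test,
    SplitTest,
    TSPTest,
    WTSPTest,
    family_of,
    render,
)

FORMAT_NAME = "mixtree-tree"
FORMAT_VERSION = "1.0"


def schema_text() -> str:
    """The shipped JSON-Schema document, as text."""
    return (
        resources.files("mixtree").joinpath("tree.schema.json").read_text("utf-8")
    )


# -- export ----------------------------------------------------------------

def _test_to_obj(test: SplitTest) -> dict:
    fam = family_of(test)
    obj: dict = {"family": fam}
    if isinstance(test, C45Test):
        obj["mode"] = test.mode
        obj["attribute"] = test.attribute
        if test.mode == THRESHOLD:
            obj["threshold"] = float(test.threshold)
        else:
            obj["category"] = test.category
    else:
        obj["attribute1"] = test.attribute1
        obj["attribute2"] = test.attribute2
        if isinstance(test, WTSPTest):
            obj["weight"] = float(test.weight)
    obj["repr"] = render(test)
    return obj


def _node_to_obj(node: TreeNode, class_levels: list[str]) -> dict:
    if node.is_leaf:
        return {
            "kind": LEAF,
            "id": node.id,
            "predicted_class": class_levels[node.predicted_class],
            "train_counts": [int(c) for c in node.train_counts],
        }
    return {
        "kind": INTERNAL,
        "id": node.id,
        "test": _test_to_obj(node.test),
        "train_counts": [int(c) for c in node.train_counts],
        "left": _node_to_obj(node.left, class_levels),
        "right": _node_to_obj(node.right, class_levels),
    }


def export_tree(tree: Tree) -> str:
    """Serialise a tree to canonical JSON text."""
    cfg = tree.config
    doc = {
        "format": FORMAT_NAME,
        "format_version": FORMAT_VERSION,
        "routing": "satisfying instances go to the left child",
        "class_levels": list(tree.class_levels),
        "attributes": [
            {
                "name": a.name,
                "kind": a.kind,
                "ignored": bool(a.ignored),
                **(
                    {"categories": list(a.categories)}
                    if a.kind == NOMINAL and a.categories is not None
                    else {}
                ),
            }
            for a in tree.attributes
        ],
        "config": {
            "families": list(cfg.families),
            "min_node_size": cfg.min_node_size,
            "max_depth": cfg.max_depth,
            "max_nodes": cfg.max_nodes,
            "entropy_threshold": float(cfg.entropy_threshold),
            "suggestion_k": cfg.suggestion_k,
            "max_pairs": cfg.max_pairs,
        },
        "root": _node_to_obj(tree.root, list(tree.class_levels)),
    }
    return json.dumps(doc, indent=2, ensure_ascii=False) + "\n"


def write_tree(tree: Tree, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(export_tree(tree))


# -- import ----------------------------------------------------------------

def _err(path: str, msg: str) -> FormatError:
    return FormatError(f"at {path}: {msg}")


def _require(obj: dict, key: str, types, path: str):
    if key not in obj:
        raise _err(path, f"missing required key {key!r}")
    v = obj[key]
    if not isinstance(v, types):
        raise _err(path, f"key {key!r} has wrong type {type(v).__name__}")
    return v


def _parse_test_obj(obj: dict, path: str, attr_by_name: dict) -> SplitTest:
    fam = _require(obj, "family", str, path)

    def _attr(key: str, kinds=(CONTINUOUS,)):
        name = _require(obj, key, str, path)
        if name not in attr_by_name:
            raise ResolutionError(f"at {path}: unknown attribute {name!r}")
        if attr_by_name[name].kind not in kinds:
            raise _err(path, f"attribute {name!r} has wrong kind for this test")
        return name

    if fam == FAMILY_C45:
        mode = _require(obj, "mode", str, path)
        if mode == THRESHOLD:
            t = _require(obj, "threshold", (int, float), path)
            return C45Test(_attr("attribute"), THRESHOLD, threshold=float(t))
        if mode == CATEGORY:
            c = _require(obj, "category", str, path)
            return C45Test(_attr("attribute", (NOMINAL,)), CATEGORY, category=c)
        raise _err(path, f"unknown C4.5 mode {mode!r}")
    if fam == FAMILY_TSP:
        return TSPTest(_attr("attribute1"), _attr("attribute2"))
    if fam == FAMILY_WTSP:
        w = _require(obj, "weight", (int, float), path)
        if not float(w) > 0:
            raise _err(path, "weight must be positive")
        return WTSPTest(_attr("attribute1"), _attr("attribute2"), float(w))
    raise _err(path, f"unknown test family {fam!r}")


def _parse_node_obj(
    obj, path: str, depth: int, class_levels: list[str], attr_by_name: dict
) -> TreeNode:
    if not isinstance(obj, dict):
        raise _err(path, "node must be an object")
    kind = _require(obj, "kind", str, path)
    counts = _require(obj, "train_counts", list, path)
    if len(counts) != len(class_levels) or not all(
        isinstance(c, int) and c >= 0 for c in counts
    ):
        raise _err(path, "train_counts must list one non-negative count per class")
    counts = np.array(counts, dtype=np.int64)
    if kind == LEAF:
        label = _require(obj, "predicted_class", str, path)
        if label not in class_levels:
            raise _err(path, f"predicted_class {label!r} not a class level")
        if "test" in obj or "left" in obj or "right" in obj:
            raise _err(path, "leaf must not carry a test or children")
        return TreeNode(
            id=str(obj.get("id", "")),
            kind=LEAF,
            depth=depth,
            train_counts=counts,
            predicted_class=class_levels.index(label),
        )
    if kind != INTERNAL:
        raise _err(path, f"unknown node kind {kind!r}")
    test = _parse_test_obj(_require(obj, "test", dict, path), path + ".test", attr_by_name)
    left = _parse_node_obj(
        _require(obj, "left", dict, path), path + ".left", depth + 1,
        class_levels, attr_by_name,
    )
    right = _parse_node_obj(
        _require(obj, "right", dict, path), path + ".right", depth + 1,
        class_levels, attr_by_name,
    )
    if not np.array_equal(left.train_counts + right.train_counts, counts):
        raise _err(path, "children train_counts do not sum to the parent's")
    return TreeNode(
        id=str(obj.get("id", "")),
        kind=INTERNAL,
        depth=depth,
        train_counts=counts,
        test=test,
        left=left,
        right=right,
    )


def import_tree(text: str, expected_schema: Dataset | None = None) -> Tree:
    """Parse and validate a tree document.

    ``expected_schema`` (a dataset) additionally requires the document's
    attribute names and kinds to match that dataset's.
    """
    try:
        doc = json.loads(text)
    except json.JSONDecodeError as exc:
        raise FormatError(f"not valid JSON: {exc}") from exc
    if not isinstance(doc, dict):
        raise FormatError("at $: document must be a JSON object")
    if doc.get("format") != FORMAT_NAME:
        raise FormatError(f"at $.format: expected {FORMAT_NAME!r}")
    version = doc.get("format_version")
    if version != FORMAT_VERSION:
        raise VersionError(
            f"at $.format_version: unsupported version {version!r} "
            f"(supported: {FORMAT_VERSION!r})"
        )
    class_levels = _require(doc, "class_levels", list, "$")
    if not class_levels or not all(isinstance(c, str) for c in class_levels):
        raise _err("$.class_levels", "must be a non-empty list of labels")
    raw_attrs = _require(doc, "attributes", list, "$")
    attrs: list[AttributeMeta] = []
    for i, a in enumerate(raw_attrs):
        p = f"$.attributes[{i}]"
        if not isinstance(a, dict):
            raise _err(p, "must be an object")
        name = _require(a, "name", str, p)
        kind = _require(a, "kind", str, p)
        if kind not in (CONTINUOUS, NOMINAL):
            raise _err(p, f"unknown kind {kind!r}")
        cats = a.get("categories")
        if cats is not None and (
            kind != NOMINAL or not all(isinstance(c, str) for c in cats)
        ):
            raise _err(p, "categories only valid as strings on nominal attributes")
        attrs.append(
            AttributeMeta(
                name, kind, i, bool(a.get("ignored", False)),
                tuple(cats) if cats is not None else None,
            )
        )
    if len({a.name for a in attrs}) != len(attrs):
        raise _err("$.attributes", "attribute names must be unique")
    attr_by_name = {a.name: a for a in attrs}

    cfg_obj = _require(doc, "config", dict, "$")
    try:
        config = InductionConfig(
            families=tuple(cfg_obj.get("families", (FAMILY_C45,))),
            min_node_size=int(cfg_obj.get("min_node_size", 5)),
            max_depth=int(cfg_obj.get("max_depth", 10)),
            max_nodes=int(cfg_obj.get("max_nodes", 50)),
            entropy_threshold=float(cfg_obj.get("entropy_threshold", 0.0)),
            suggestion_k=int(cfg_obj.get("suggestion_k", 5)),
            max_pairs=cfg_obj.get("max_pairs"),
        )
    except Exception as exc:
        raise _err("$.config", str(exc)) from exc

    root = _parse_node_obj(
        _require(doc, "root", dict, "$"), "$.root", 0, class_levels, attr_by_name
    )
    tree = Tree(root, config, attrs, list(class_levels))
    assign_ids(tree)
    if expected_schema is not None:
        for a in attrs:
            try:
                b = expected_schema.attribute(a.name)
            except KeyError:
                raise ResolutionError(
                    f"dataset lacks attribute {a.name!r} named by the document"
                )
            if b.kind != a.kind:
                raise FormatError(
                    f"attribute {a.name!r}: document kind {a.kind} != dataset "
                    f"kind {b.kind}"
                )
    return tree


def read_tree(path, expected_schema: Dataset | None = None) -> Tree:
    with open(path, "r", encoding="utf-8") as fh:
        return import_tree(fh.read(), expected_schema)
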