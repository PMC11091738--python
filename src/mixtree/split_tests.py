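"""The three node-test families and instance routing.

A node test is one of:

* ``C45Test`` — univariate, axis-parallel: ``attribute >= threshold`` on a
  continuous attribute, or ``attribute == category`` on a nominal one (the
  tree stays binary, so nominal splits are one-category-vs-rest).
* ``TSPTest`` — top-scoring-pair relational test ``attribute1 < attribute2``;
  the within-sample ordering of two features, robust to monotone
  normalisation differences across platforms.
* ``WTSPTest`` — weighted pair test ``attribute1 < weight * attribute2``,
  detecting proportional (not just ordinal) shifts between two features.

Conventions (fixed, recorded in the JSON schema so trees are portable):
instances satisfying the predicate go to the LEFT child; pair comparisons
are strict, so ties route right; a nominal value outside the test category's
vocabulary also routes right.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Mapping, Union

from .dataset import CONTINUOUS, NOMINAL, Dataset
from .errors import ResolutionError, StructuralError, ExpressionParseError

LEFT = "left"
RIGHT = "right"

THRESHOLD = "threshold"
CATEGORY = "category"


@dataclass(frozen=True)
class C45Test:
    """Univariate test: ``attribute >= threshold`` or ``attribute == category``."""

    attribute: str
    mode: str  # THRESHOLD or CATEGORY
    threshold: float | None = None
    category: str | None = None

    def __post_init__(self) -> None:
        if self.mode == THRESHOLD:
            if self.threshold is None or self.category is not None:
                raise StructuralError("threshold mode requires a threshold only")
        elif self.mode == CATEGORY:
            if self.category is None or self.threshold is not None:
                raise StructuralError("category mode requires a category only")
        else:
            raise StructuralError(f"unknown C45 mode {self.mode!r}")


@dataclass(frozen=True)
class TSPTest:
    """Pair test: ``attribute1 < attribute2``."""

    attribute1: str
    attribute2: str

    def __post_init__(self) -> None:
        if self.attribute1 == self.attribute2:
            raise StructuralError("TSP test requires two distinct attributes")


@dataclass(frozen=True)
class WTSPTest:
    """Weighted pair test: ``attribute1 < weight * attribute2`` with weight > 0."""

    attribute1: str
    attribute2: str
    weight: float

    def __post_init__(self) -> None:
        if self.attribute1 == self.attribute2:
            raise StructuralError("WTSP test requires two distinct attributes")
        if not self.weight > 0:
            raise StructuralError("WTSP weight must be positive")


SplitTest = Union[C45Test, TSPTest, WTSPTest]

#: canonical family names and their tie-break order
FAMILY_C45 = "c45"
FAMILY_TSP = "tsp"
FAMILY_WTSP = "wtsp"
FAMILIES = (FAMILY_C45, FAMILY_TSP, FAMILY_WTSP)


def family_of(test: SplitTest) -> str:
    if isinstance(test, C45Test):
        return FAMILY_C45
    if isinstance(test, TSPTest):
        return FAMILY_TSP
    if isinstance(test, WTSPTest):
        return FAMILY_WTSP
    raise StructuralError(f"not a split test: {test!r}")


def validate_test(test: SplitTest, data: Dataset) -> None:
    """Check a test against a dataset schema; raise StructuralError if invalid."""
    def _attr(name: str):
        try:
            return data.attribute(name)
        except KeyError:
            raise StructuralError(f"test references unknown attribute {name!r}")

    if isinstance(test, C45Test):
        a = _attr(test.attribute)
        if test.mode == THRESHOLD and a.kind != CONTINUOUS:
            raise StructuralError(
                f"threshold test on non-continuous attribute {a.name!r}"
            )
        if test.mode == CATEGORY and a.kind != NOMINAL:
            raise StructuralError(f"category test on non-nominal attribute {a.name!r}")
    elif isinstance(test, (TSPTest, WTSPTest)):
        for name in (test.attribute1, test.attribute2):
            if _attr(name).kind != CONTINUOUS:
                raise StructuralError(
                    f"pair test on non-continuous attribute {name!r}"
                )
    else:
        raise StructuralError(f"not a split test: {test!r}")


def route(test: SplitTest, instance: Mapping[str, object]) -> str:
    """Route one instance through a test; returns ``"left"`` iff the predicate holds.

    Pure and deterministic: ties in pair comparisons and out-of-vocabulary
    nominal values route right.
    """
    def _value(name: str):
        try:
            return instance[name]
        except KeyError:
            raise StructuralError(f"instance lacks attribute {name!r}")

    if isinstance(test, C45Test):
        v = _value(test.attribute)
        if test.mode == THRESHOLD:
            return LEFT if float(v) >= test.threshold else RIGHT
        return LEFT if v == test.category else RIGHT
    if isinstance(test, TSPTest):
        return LEFT if float(_value(test.attribute1)) < float(_value(test.attribute2)) else RIGHT
    if isinstance(test, WTSPTest):
        v1 = float(_value(test.attribute1))
        v2 = float(_value(test.attribute2))
        return LEFT if v1 < test.weight * v2 else RIGHT
    raise StructuralError(f"not a split test: {test!r}")


def route_mask(test: SplitTest, data: Dataset, rows=None):
    """Vectorised routing: boolean array, True where the row goes left."""
    import numpy as np

    if isinstance(test, C45Test):
        col = data.column(test.attribute)
        col = col if rows is None else col[rows]
        if test.mode == THRESHOLD:
            return col.astype(np.float64) >= test.threshold
        return np.array([v == test.category for v in col], dtype=bool)
    v1 = data.column(test.attribute1).astype("float64")
    v2 = data.column(test.attribute2).astype("float64")
    if rows is not None:
        v1, v2 = v1[rows], v2[rows]
    if isinstance(test, TSPTest):
        return v1 < v2
    return v1 < test.weight * v2


# -- canonical text form ---------------------------------------------------

def _fmt(x: float) -> str:
    """Shortest decimal form that round-trips to the same float."""
    return repr(float(x))


def render(test: SplitTest) -> str:
    """Canonical one-line form, parseable back by :func:`parse_test`.

    Examples: ``g1 >= 3.5``, ``g1 == red``, ``g1 < g2``, ``g1 < 1.25 * g2``.
    """
    if isinstance(test, C45Test):
        if test.mode == THRESHOLD:
            return f"{test.attribute} >= {_fmt(test.threshold)}"
        return f"{test.attribute} == {test.category}"
    if isinstance(test, TSPTest):
        return f"{test.attribute1} < {test.attribute2}"
    if isinstance(test, WTSPTest):
        return f"{test.attribute1} < {_fmt(test.weight)} * {test.attribute2}"
    raise StructuralError(f"not a split test: {test!r}")


_NUM = r"[-+]?(?:\d+\.?\d*|\.\d+)(?:[eE][-+]?\d+)?"
_RE_GE = re.compile(rf"^\s*(?P<a>.+?)\s*>=\s*(?P<t>{_NUM})\s*$")
_RE_EQ = re.compile(r"^\s*(?P<a>.+?)\s*==\s*(?P<c>.+?)\s*$")
_RE_WTSP = re.compile(rf"^\s*(?P<a>.+?)\s*<\s*(?P<w>{_NUM})\s*\*\s*(?P<b>.+?)\s*$")
_RE_TSP = re.compile(r"^\s*(?P<a>.+?)\s*<\s*(?P<b>.+?)\s*$")


def parse_test(text: str, data: Dataset) -> SplitTest:
    """Parse the canonical grammar back into a test, resolving names
    against the dataset schema.  Inverse of :func:`render` up to numeric
    formatting."""
    def _resolve(name: str) -> str:
        try:
            data.attribute(name)
        except KeyError:
            raise ResolutionError(f"unknown attribute {name!r} in test {text!r}")
        return name

    m = _RE_GE.match(text)
    if m:
        t = C45Test(_resolve(m["a"]), THRESHOLD, threshold=float(m["t"]))
        validate_test(t, data)
        return t
    m = _RE_EQ.match(text)
    if m:
        t = C45Test(_resolve(m["a"]), CATEGORY, category=m["c"])
        validate_test(t, data)
        return t
    m = _RE_WTSP.match(text)
    if m:
        # "a < 2 * b": prefer WTSP reading unless "2 * b" is itself an attribute
        try:
            data.attribute(f"{m['w']} * {m['b']}")
        except KeyError:
            t = WTSPTest(_resolve(m["a"]), _resolve(m["b"]), float(m["w"]))
            validate_test(t, data)
            return t
    m = _RE_TSP.match(text)
    if m:
        t = TSPTest(_resolve(m["a"]), _resolve(m["b"]))
        validate_test(t, data)
        return t
    raise ExpressionParseError(f"cannot parse test expression {text!r}")
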