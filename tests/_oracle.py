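"""Independent brute-force split-search oracle.

Pure-Python enumeration of the entire candidate space of each test family,
written without reference to the library's search code (only plain loops
and ``math.log2``).  Shares the library's *documented conventions*: gain
ratio criterion, midpoints between consecutive distinct values/ratios as
candidates, a midpoint must sit strictly above its lower neighbour, splits
need more than 1e-12 bits of information gain, and the canonical tie-break
(higher gain ratio, higher info gain, family order c45 < tsp < wtsp, lowest
attribute indices, smallest threshold/weight, earliest category).
"""

from __future__ import annotations

import math

MIN_GAIN = 1e-12
FAMILY_RANK = {"c45": 0, "tsp": 1, "wtsp": 2}


def entropy(counts) -> float:
    n = sum(counts)
    h = 0.0
    for c in counts:
        if c > 0:
            p = c / n
            h -= p * math.log2(p)
    return h


def stats(parent, left):
    right = [p - l for p, l in zip(parent, left)]
    n, nl, nr = sum(parent), sum(left), sum(right)
    if nl == 0 or nr == 0:
        return None
    ig = entropy(parent) - (nl / n) * entropy(left) - (nr / n) * entropy(right)
    pl, pr = nl / n, nr / n
    si = -(pl * math.log2(pl) + pr * math.log2(pr))
    return ig / si, ig, si


class Candidate:
    def __init__(self, family, key_tail, gr, ig, si, left, describe):
        self.family = family
        self.gr, self.ig, self.si = gr, ig, si
        self.left = left
        self.describe = describe  # comparable description of the test
        self.key = (-gr, -ig, FAMILY_RANK[family]) + tuple(key_tail)


def _counts(labels, members, n_classes):
    out = [0] * n_classes
    for i in members:
        out[labels[i]] += 1
    return out


def _candidate(family, key_tail, parent, left_counts, describe):
    st = stats(parent, left_counts)
    if st is None:
        return None
    gr, ig, si = st
    if ig <= MIN_GAIN:
        return None
    return Candidate(family, key_tail, gr, ig, si, left_counts, describe)


def c45_candidates(columns, kinds, categories, labels, n_classes, min_child=1):
    """columns: list of per-attribute value lists (rows already selected)."""
    n = len(labels)
    parent = _counts(labels, range(n), n_classes)
    out = []
    for ai, vals in enumerate(columns):
        if kinds[ai] == "ignored":
            continue
        if kinds[ai] == "continuous":
            distinct = sorted(set(vals))
            for lo, hi in zip(distinct, distinct[1:]):
                t = (lo + hi) / 2.0
                if not t > lo:
                    continue
                members = [i for i in range(n) if vals[i] >= t]
                if len(members) < min_child or n - len(members) < min_child:
                    continue
                c = _candidate(
                    "c45", (ai, -1, t), parent,
                    _counts(labels, members, n_classes),
                    ("c45", ai, "threshold", t),
                )
                if c:
                    out.append(c)
        else:
            for ci, cat in enumerate(categories[ai]):
                members = [i for i in range(n) if vals[i] == cat]
                if (
                    len(members) < min_child
                    or n - len(members) < min_child
                ):
                    continue
                c = _candidate(
                    "c45", (ai, -1, float(ci)), parent,
                    _counts(labels, members, n_classes),
                    ("c45", ai, "category", cat),
                )
                if c:
                    out.append(c)
    return out


def tsp_candidates(columns, kinds, labels, n_classes, min_child=1):
    n = len(labels)
    parent = _counts(labels, range(n), n_classes)
    cont = [i for i, k in enumerate(kinds) if k == "continuous"]
    out = []
    for i in cont:
        for j in cont:
            if i == j:
                continue
            members = [r for r in range(n) if columns[i][r] < columns[j][r]]
            if len(members) < min_child or n - len(members) < min_child:
                continue
            c = _candidate(
                "tsp", (i, j, 0.0), parent,
                _counts(labels, members, n_classes),
                ("tsp", i, j),
            )
            if c:
                out.append(c)
    return out


def wtsp_candidates(columns, kinds, labels, n_classes, min_child=1):
    n = len(labels)
    parent = _counts(labels, range(n), n_classes)
    cont = [i for i, k in enumerate(kinds) if k == "continuous"]
    out = []
    for i in cont:
        for j in cont:
            if i == j:
                continue
            if any(columns[j][r] <= 0 for r in range(n)):
                continue
            ratios = [columns[i][r] / columns[j][r] for r in range(n)]
            distinct = sorted(set(ratios))
            for lo, hi in zip(distinct, distinct[1:]):
                w = (lo + hi) / 2.0
                if not (w > lo and w > 0):
                    continue
                members = [r for r in range(n) if ratios[r] < w]
                if len(members) < min_child or n - len(members) < min_child:
                    continue
                c = _candidate(
                    "wtsp", (i, j, w), parent,
                    _counts(labels, members, n_classes),
                    ("wtsp", i, j, w),
                )
                if c:
                    out.append(c)
    return out


def best(cands):
    if not cands:
        return None
    return min(cands, key=lambda c: c.key)


def dataset_columns(data):
    """Extract plain-Python columns / kinds / categories from a Dataset."""
    columns, kinds, categories = [], [], []
    for a in data.attributes:
        col = list(data.column(a.name))
        if a.kind == "continuous":
            col = [float(v) for v in col]
        columns.append(col)
        kinds.append("ignored" if a.ignored else a.kind)
        categories.append(list(a.categories or ()))
    return columns, kinds, categories


def describe_test(test, data):
    """Map a library SplitTest to the oracle's comparable description."""
    from mixtree.split_tests import C45Test, TSPTest, WTSPTest

    idx = {a.name: i for i, a in enumerate(data.attributes)}
    if isinstance(test, C45Test):
        if test.mode == "threshold":
            return ("c45", idx[test.attribute], "threshold", test.threshold)
        return ("c45", idx[test.attribute], "category", test.category)
    if isinstance(test, TSPTest):
        return ("tsp", idx[test.attribute1], idx[test.attribute2])
    if isinstance(test, WTSPTest):
        return ("wtsp", idx[test.attribute1], idx[test.attribute2], test.weight)
    raise TypeError(test)
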