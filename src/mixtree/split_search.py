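"""Entropy / gain-ratio machinery and exhaustive best-split search.

The splitting criterion is the gain ratio (information gain divided by the
split information, both in bits) for all three test families, as in C4.5.
Candidate sets are exhaustive:

* continuous C4.5 thresholds — midpoints between consecutive distinct sorted
  values present at the node;
* nominal C4.5 — one binary ``== category`` test per category present;
* TSP — every ordered pair of distinct non-ignored continuous attributes;
* WTSP — for every ordered pair whose second attribute is strictly positive
  on all node rows, weight candidates at midpoints between consecutive
  distinct per-row ratios v1/v2.  The predicate ``v1 < w * v2`` only changes
  at observed ratios, so this finds the optimum over all real weights.

Ties are broken deterministically: higher gain ratio, then higher
information gain, then family order C4.5 < TSP < WTSP, then lowest attribute
index (then second attribute index, then smaller threshold / earlier
category / smaller weight).

Numerical conventions: a split must improve information by more than
``MIN_GAIN`` bits (guards against float noise re-creating the parent
distribution); a midpoint that rounds onto its lower neighbour (adjacent
floats) is skipped so that counted partitions always equal predicate
routing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dataset import CONTINUOUS, NOMINAL, AttributeMeta, Dataset
from .errors import (
    DegenerateSplitError,
    InputError,
    NotApplicableError,
    StructuralError,
)
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
)

#: minimum information gain (bits) for a split to count as informative
MIN_GAIN = 1e-12

_FAMILY_RANK = {FAMILY_C45: 0, FAMILY_TSP: 1, FAMILY_WTSP: 2}


@dataclass(frozen=True)
class ScoredSplit:
    """A candidate split with its gain-ratio statistics and child class counts."""

    test: SplitTest
    gain_ratio: float
    info_gain: float
    split_info: float
    left_counts: np.ndarray
    right_counts: np.ndarray


def entropy(counts) -> float:
    """Shannon entropy, in bits, of a class-count vector."""
    c = np.asarray(counts, dtype=np.float64)
    n = c.sum()
    if n < 1:
        raise InputError("entropy of an empty count vector is undefined")
    p = c[c > 0] / n
    return float(-(p * np.log2(p)).sum())


def gain_ratio(parent, left, right) -> tuple[float, float, float]:
    """Gain-ratio statistics of a binary partition of ``parent``.

    Returns ``(gain_ratio, info_gain, split_info)``.  Raises
    :class:`DegenerateSplitError` if a side is empty (its split information
    would be zero); such splits are excluded from every search.
    """
    parent = np.asarray(parent, dtype=np.int64)
    left = np.asarray(left, dtype=np.int64)
    right = np.asarray(right, dtype=np.int64)
    if not np.array_equal(left + right, parent):
        raise StructuralError("left + right counts must equal parent counts")
    n, nl, nr = parent.sum(), left.sum(), right.sum()
    if nl == 0 or nr == 0:
        raise DegenerateSplitError("a split side is empty")
    ig = entropy(parent) - (nl / n) * entropy(left) - (nr / n) * entropy(right)
    pl, pr = nl / n, nr / n
    si = -(pl * np.log2(pl) + pr * np.log2(pr))
    return float(ig / si), float(ig), float(si)


# -- vectorised scoring ----------------------------------------------------

def _entropy_rows(counts: np.ndarray) -> np.ndarray:
    """Entropy (bits) of each row of a (m, C) count matrix; 0 for empty rows."""
    c = counts.astype(np.float64)
    n = c.sum(axis=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.where(n > 0, c / np.where(n > 0, n, 1.0), 0.0)
        t = np.where(p > 0, -p * np.log2(np.where(p > 0, p, 1.0)), 0.0)
    return t.sum(axis=1)


def _score_partitions(left_counts: np.ndarray, parent_counts: np.ndarray):
    """Gain-ratio stats for m candidate partitions given by their left counts.

    Returns (gr, ig, si, valid) arrays; ``valid`` requires both sides
    non-empty and info gain above ``MIN_GAIN``.
    """
    parent_counts = np.asarray(parent_counts, dtype=np.int64)
    n = parent_counts.sum()
    right_counts = parent_counts[None, :] - left_counts
    nl = left_counts.sum(axis=1)
    nr = n - nl
    hp = entropy(parent_counts)
    hl = _entropy_rows(left_counts)
    hr = _entropy_rows(right_counts)
    ig = hp - (nl / n) * hl - (nr / n) * hr
    with np.errstate(divide="ignore", invalid="ignore"):
        pl = nl / n
        pr = nr / n
        si = -(
            np.where(pl > 0, pl * np.log2(np.where(pl > 0, pl, 1.0)), 0.0)
            + np.where(pr > 0, pr * np.log2(np.where(pr > 0, pr, 1.0)), 0.0)
        )
        gr = np.where(si > 0, ig / np.where(si > 0, si, 1.0), 0.0)
    valid = (nl > 0) & (nr > 0) & (ig > MIN_GAIN)
    return gr, ig, si, valid


def sort_key(split: ScoredSplit, data: Dataset) -> tuple:
    """Total order over candidate splits; ``min`` picks the canonical best."""
    t = split.test
    fam = _FAMILY_RANK[family_of(t)]
    if isinstance(t, C45Test):
        a = data.attribute(t.attribute)
        if t.mode == THRESHOLD:
            value = float(t.threshold)
        else:
            value = float(a.categories.index(t.category))
        return (-split.gain_ratio, -split.info_gain, fam, a.index, -1, value)
    i1 = data.attribute(t.attribute1).index
    i2 = data.attribute(t.attribute2).index
    value = float(t.weight) if isinstance(t, WTSPTest) else 0.0
    return (-split.gain_ratio, -split.info_gain, fam, i1, i2, value)


def _resolve_rows(data: Dataset, rows) -> np.ndarray:
    if rows is None:
        return np.arange(data.n_samples)
    return np.asarray(rows, dtype=np.int64)


# -- C4.5 ------------------------------------------------------------------

def best_c45_split(
    data: Dataset,
    rows=None,
    attribute: AttributeMeta | str | None = None,
    *,
    min_child_size: int = 1,
) -> ScoredSplit | None:
    """Best univariate split.

    With ``attribute`` given, searches only that attribute (its optimal
    threshold if continuous, its best ``== category`` test if nominal);
    otherwise searches every non-ignored attribute.  Returns ``None`` when
    no candidate is non-degenerate with positive information gain.
    """
    cands = _c45_candidates(data, rows, attribute, min_child_size)
    if not cands:
        return None
    return min(cands, key=lambda s: sort_key(s, data))


def _c45_candidates(
    data: Dataset, rows, attribute, min_child_size: int
) -> list[ScoredSplit]:
    rows = _resolve_rows(data, rows)
    if attribute is None:
        attrs = data.active_attributes()
    else:
        if isinstance(attribute, str):
            attribute = data.attribute(attribute)
        if attribute.ignored:
            raise StructuralError(f"attribute {attribute.name!r} is ignored")
        attrs = [attribute]
    y = data.labels[rows]
    parent = np.bincount(y, minlength=data.n_classes).astype(np.int64)
    out: list[ScoredSplit] = []
    for a in attrs:
        if a.kind == CONTINUOUS:
            s = _best_threshold(data, rows, y, parent, a, min_child_size)
        else:
            s = _best_category(data, rows, y, parent, a, min_child_size)
        if s is not None:
            out.append(s)
    return out


def _prefix_counts(y_sorted: np.ndarray, n_classes: int) -> np.ndarray:
    """(n+1, C) matrix: prefix[k] = class counts of the first k sorted rows."""
    onehot = (y_sorted[:, None] == np.arange(n_classes)[None, :]).astype(np.int64)
    prefix = np.zeros((len(y_sorted) + 1, n_classes), dtype=np.int64)
    prefix[1:] = np.cumsum(onehot, axis=0)
    return prefix


def _best_threshold(data, rows, y, parent, attr, min_child_size):
    vals = data.column(attr.name).astype(np.float64)[rows]
    order = np.argsort(vals, kind="stable")
    vs, ys = vals[order], y[order]
    n = len(vs)
    if n < 2:
        return None
    prefix = _prefix_counts(ys, data.n_classes)
    cuts = np.nonzero(vs[:-1] != vs[1:])[0] + 1  # split before sorted position k
    if len(cuts) == 0:
        return None
    thresholds = (vs[cuts - 1] + vs[cuts]) / 2.0
    ok = thresholds > vs[cuts - 1]  # midpoint must sit strictly above the lower value
    cuts, thresholds = cuts[ok], thresholds[ok]
    if len(cuts) == 0:
        return None
    # v >= threshold goes LEFT, so left counts are the suffix counts
    left_counts = parent[None, :] - prefix[cuts]
    gr, ig, si, valid = _score_partitions(left_counts, parent)
    nl = left_counts.sum(axis=1)
    valid &= (nl >= min_child_size) & ((n - nl) >= min_child_size)
    if not valid.any():
        return None
    idx = np.nonzero(valid)[0]
    # tie-break within the attribute: higher gr, higher ig, smaller threshold
    order2 = np.lexsort((thresholds[idx], -ig[idx], -gr[idx]))
    k = idx[order2[0]]
    lc = left_counts[k]
    return ScoredSplit(
        C45Test(attr.name, THRESHOLD, threshold=float(thresholds[k])),
        float(gr[k]), float(ig[k]), float(si[k]), lc, parent - lc,
    )


def _best_category(data, rows, y, parent, attr, min_child_size):
    col = data.column(attr.name)[rows]
    best = None
    best_key = None
    for ci, cat in enumerate(attr.categories or ()):
        mask = np.array([v == cat for v in col], dtype=bool)
        nl = int(mask.sum())
        nr = len(col) - nl
        if nl < min_child_size or nr < min_child_size or nl == 0 or nr == 0:
            continue
        lc = np.bincount(y[mask], minlength=data.n_classes).astype(np.int64)
        gr, ig, si = gain_ratio(parent, lc, parent - lc)
        if ig <= MIN_GAIN:
            continue
        key = (-gr, -ig, ci)
        if best_key is None or key < best_key:
            best_key = key
            best = ScoredSplit(
                C45Test(attr.name, CATEGORY, category=cat),
                gr, ig, si, lc, parent - lc,
            )
    return best


# -- pair tests ------------------------------------------------------------

@dataclass(frozen=True)
class PairFilter:
    """Constraints on the ordered-pair searches (used by partial-test
    completion): fix the first attribute, the second, or (WTSP) the weight."""

    attribute1: str | None = None
    attribute2: str | None = None
    weight: float | None = None


def _eligible_pair_attrs(data: Dataset, rows, max_pairs):
    attrs = data.active_attributes(CONTINUOUS)
    if len(attrs) < 2:
        raise NotApplicableError(
            "pair tests require at least two non-ignored continuous attributes"
        )
    if max_pairs is not None and len(attrs) * (len(attrs) - 1) > max_pairs:
        # variance-ranked prefilter; keep the largest m with m*(m-1) <= max_pairs
        m = 2
        while (m + 1) * m <= max_pairs:
            m += 1
        X = data.continuous_matrix([a.name for a in attrs])[rows]
        var = X.var(axis=0)
        order = np.lexsort((np.arange(len(attrs)), -var))
        keep = sorted(order[:m])
        attrs = [attrs[i] for i in keep]
    return attrs


def _apply_pair_filter(attrs, pair_filter, data):
    a1s = attrs
    a2s = attrs
    if pair_filter is not None:
        if pair_filter.attribute1 is not None:
            a = data.attribute(pair_filter.attribute1)
            if a.kind != CONTINUOUS or a.ignored:
                raise StructuralError(
                    f"pair attribute {a.name!r} must be continuous and not ignored"
                )
            a1s = [a]
        if pair_filter.attribute2 is not None:
            a = data.attribute(pair_filter.attribute2)
            if a.kind != CONTINUOUS or a.ignored:
                raise StructuralError(
                    f"pair attribute {a.name!r} must be continuous and not ignored"
                )
            a2s = [a]
        if (
            pair_filter.attribute1 is not None
            and pair_filter.attribute1 == pair_filter.attribute2
        ):
            raise StructuralError("pair test requires two distinct attributes")
    return a1s, a2s


def _tsp_candidates(
    data: Dataset, rows, pair_filter, min_child_size, max_pairs
) -> list[ScoredSplit]:
    rows = _resolve_rows(data, rows)
    attrs = _eligible_pair_attrs(data, rows, max_pairs)
    a1s, a2s = _apply_pair_filter(attrs, pair_filter, data)
    y = data.labels[rows]
    parent = np.bincount(y, minlength=data.n_classes).astype(np.int64)
    X1 = data.continuous_matrix([a.name for a in a1s])[rows]
    X2 = data.continuous_matrix([a.name for a in a2s])[rows]
    # less[r, i, j] == True iff row r satisfies a1s[i] < a2s[j]
    less = X1[:, :, None] < X2[:, None, :]
    C = data.n_classes
    left_counts = np.zeros((len(a1s), len(a2s), C), dtype=np.int64)
    for c in range(C):
        left_counts[:, :, c] = less[y == c].sum(axis=0)
    flat = left_counts.reshape(-1, C)
    gr, ig, si, valid = _score_partitions(flat, parent)
    nl = flat.sum(axis=1)
    n = len(rows)
    valid &= (nl >= min_child_size) & ((n - nl) >= min_child_size)
    out: list[ScoredSplit] = []
    n2 = len(a2s)
    for k in np.nonzero(valid)[0]:
        i, j = divmod(int(k), n2)
        if a1s[i].name == a2s[j].name:
            continue
        lc = flat[k]
        out.append(
            ScoredSplit(
                TSPTest(a1s[i].name, a2s[j].name),
                float(gr[k]), float(ig[k]), float(si[k]), lc, parent - lc,
            )
        )
    return out


def best_tsp_split(
    data: Dataset,
    rows=None,
    pair_filter: PairFilter | None = None,
    *,
    min_child_size: int = 1,
    max_pairs: int | None = None,
) -> ScoredSplit | None:
    """Best ``attribute1 < attribute2`` split over all ordered attribute pairs."""
    cands = _tsp_candidates(data, rows, pair_filter, min_child_size, max_pairs)
    if not cands:
        return None
    return min(cands, key=lambda s: sort_key(s, data))


def _wtsp_pair_best(
    r: np.ndarray,
    y: np.ndarray,
    parent: np.ndarray,
    min_child_size: int,
    fixed_weight: float | None,
):
    """Best weight for one pair given per-row ratios r = v1/v2 (v2 > 0)."""
    n = len(r)
    if fixed_weight is not None:
        if not fixed_weight > 0:
            raise StructuralError("WTSP weight must be positive")
        lc_mask = r < fixed_weight
        nl = int(lc_mask.sum())
        if nl < min_child_size or (n - nl) < min_child_size or nl == 0 or nl == n:
            return None
        lc = np.bincount(y[lc_mask], minlength=len(parent)).astype(np.int64)
        try:
            gr, ig, si = gain_ratio(parent, lc, parent - lc)
        except DegenerateSplitError:
            return None
        if ig <= MIN_GAIN:
            return None
        return float(fixed_weight), gr, ig, si, lc
    order = np.argsort(r, kind="stable")
    rs, ys = r[order], y[order]
    prefix = _prefix_counts(ys, len(parent))
    cuts = np.nonzero(rs[:-1] != rs[1:])[0] + 1
    if len(cuts) == 0:
        return None
    weights = (rs[cuts - 1] + rs[cuts]) / 2.0
    ok = (weights > rs[cuts - 1]) & (weights > 0)
    cuts, weights = cuts[ok], weights[ok]
    if len(cuts) == 0:
        return None
    left_counts = prefix[cuts]  # ratio < w goes LEFT
    gr, ig, si, valid = _score_partitions(left_counts, parent)
    nl = cuts
    valid &= (nl >= min_child_size) & ((n - nl) >= min_child_size)
    if not valid.any():
        return None
    idx = np.nonzero(valid)[0]
    order2 = np.lexsort((weights[idx], -ig[idx], -gr[idx]))
    k = idx[order2[0]]
    return float(weights[k]), float(gr[k]), float(ig[k]), float(si[k]), left_counts[k]


def _wtsp_candidates(
    data: Dataset, rows, pair_filter, min_child_size, max_pairs
) -> list[ScoredSplit]:
    rows = _resolve_rows(data, rows)
    attrs = _eligible_pair_attrs(data, rows, max_pairs)
    a1s, a2s = _apply_pair_filter(attrs, pair_filter, data)
    fixed_w = pair_filter.weight if pair_filter is not None else None
    y = data.labels[rows]
    parent = np.bincount(y, minlength=data.n_classes).astype(np.int64)
    cols = {a.name: data.column(a.name).astype(np.float64)[rows] for a in set(a1s) | set(a2s)}
    positive = {name: bool((v > 0).all()) for name, v in cols.items()}
    out: list[ScoredSplit] = []
    for a1 in a1s:
        v1 = cols[a1.name]
        for a2 in a2s:
            if a1.name == a2.name:
                continue
            if not positive[a2.name]:
                continue  # ratio undefined: denominator not strictly positive
            res = _wtsp_pair_best(
                v1 / cols[a2.name], y, parent, min_child_size, fixed_w
            )
            if res is None:
                continue
            w, gr, ig, si, lc = res
            out.append(
                ScoredSplit(
                    WTSPTest(a1.name, a2.name, w), gr, ig, si, lc, parent - lc
                )
            )
    return out


def best_wtsp_split(
    data: Dataset,
    rows=None,
    pair_filter: PairFilter | None = None,
    *,
    min_child_size: int = 1,
    max_pairs: int | None = None,
) -> ScoredSplit | None:
    """Best ``attribute1 < weight * attribute2`` split.

    Pairs with any non-positive denominator value among the node rows are
    skipped entirely (expression data is non-negative; ratio semantics are
    otherwise undefined).  Weight candidates are ratio midpoints; scoring is
    over ALL node rows.
    """
    cands = _wtsp_candidates(data, rows, pair_filter, min_child_size, max_pairs)
    if not cands:
        return None
    return min(cands, key=lambda s: sort_key(s, data))


# -- pooled search, suggestions, completion --------------------------------

_BEST = {
    FAMILY_C45: lambda d, r, mcs, mp: _c45_candidates(d, r, None, mcs),
    FAMILY_TSP: lambda d, r, mcs, mp: _tsp_candidates(d, r, None, mcs, mp),
    FAMILY_WTSP: lambda d, r, mcs, mp: _wtsp_candidates(d, r, None, mcs, mp),
}


def _pooled_candidates(data, rows, families, min_child_size, max_pairs):
    cands: list[ScoredSplit] = []
    for fam in (FAMILY_C45, FAMILY_TSP, FAMILY_WTSP):
        if fam not in families:
            continue
        try:
            cands.extend(_BEST[fam](data, rows, min_child_size, max_pairs))
        except NotApplicableError:
            continue  # family not applicable here; others may still apply
    return cands


def search_best_split(
    data: Dataset,
    rows=None,
    families=(FAMILY_C45,),
    *,
    min_child_size: int = 1,
    max_pairs: int | None = None,
) -> ScoredSplit | None:
    """Canonical best split across the enabled families (None if no split
    has positive information gain under the child-size constraint)."""
    cands = _pooled_candidates(data, rows, families, min_child_size, max_pairs)
    if not cands:
        return None
    return min(cands, key=lambda s: sort_key(s, data))


def suggest_top_splits(
    data: Dataset,
    rows=None,
    families=(FAMILY_C45, FAMILY_TSP, FAMILY_WTSP),
    k: int = 5,
    *,
    min_child_size: int = 1,
    max_pairs: int | None = None,
) -> list[ScoredSplit]:
    """The k highest-gain-ratio non-degenerate splits pooled across the
    enabled families, sorted descending with the canonical tie-break;
    duplicate tests removed.  May be shorter than k (empty on a pure node)."""
    if k < 1:
        raise InputError("k must be a positive integer")
    cands = _pooled_candidates(data, rows, families, min_child_size, max_pairs)
    cands.sort(key=lambda s: sort_key(s, data))
    out: list[ScoredSplit] = []
    seen = set()
    for s in cands:
        if s.test in seen:
            continue
        seen.add(s.test)
        out.append(s)
        if len(out) == k:
            break
    return out


@dataclass(frozen=True)
class PartialTest:
    """A test with some parameters fixed and the rest left to the search.

    ``family`` is mandatory; any subset of the family's parameters may be
    fixed.  For C4.5, ``attribute`` names the (single) test attribute.
    """

    family: str
    attribute: str | None = None  # C4.5
    attribute1: str | None = None  # TSP / WTSP
    attribute2: str | None = None
    weight: float | None = None  # WTSP

    def __post_init__(self) -> None:
        if self.family not in _FAMILY_RANK:
            raise StructuralError(f"unknown test family {self.family!r}")
        if (
            self.attribute1 is not None
            and self.attribute1 == self.attribute2
        ):
            raise StructuralError("pair test requires two distinct attributes")
        if self.weight is not None and not self.weight > 0:
            raise StructuralError("WTSP weight must be positive")


def complete_partial_test(
    data: Dataset,
    rows=None,
    partial: PartialTest | None = None,
    *,
    min_child_size: int = 1,
    max_pairs: int | None = None,
) -> ScoredSplit | None:
    """Fill in the free parameters of a partially specified test by
    exhaustive search over those parameters only.

    Examples: a C4.5 partial fixing only the attribute finds its optimal
    threshold (or category); a TSP partial fixing ``attribute1`` finds the
    best partner; a WTSP partial fixing both attributes finds the best
    weight.  A fully free partial degenerates to the family's best split.
    """
    if partial is None:
        raise StructuralError("a partial test specification is required")
    if partial.family == FAMILY_C45:
        return best_c45_split(
            data, rows, partial.attribute, min_child_size=min_child_size
        )
    pf = PairFilter(partial.attribute1, partial.attribute2, partial.weight)
    if partial.family == FAMILY_TSP:
        if partial.weight is not None:
            raise StructuralError("TSP tests carry no weight")
        return best_tsp_split(
            data, rows, pf, min_child_size=min_child_size, max_pairs=max_pairs
        )
    return best_wtsp_split(
        data, rows, pf, min_child_size=min_child_size, max_pairs=max_pairs
    )
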