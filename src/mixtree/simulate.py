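"""Synthetic expression-like datasets with planted rules.

The generator emulates the data regime relative-expression classifiers are
built for: strictly positive, right-skewed per-gene values (log-normal) in
which the class is determined by a *relative* relation between features
rather than by absolute levels.  A planted rule — a threshold on one
attribute, an ordering of an attribute pair, or a weighted ordering — fixes
the true label of each sample, which is then flipped independently with a
given noise rate.  All remaining attributes are uninformative decoys.

Everything is reproducible from the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Union

import numpy as np
import pandas as pd

from .dataset import CONTINUOUS, NOMINAL, AttributeMeta, Dataset
from .errors import InputError

#: class labels of generated datasets, in fixed level order
POSITIVE, NEGATIVE = "pos", "neg"


@dataclass(frozen=True)
class ThresholdRule:
    """Label = (value of attribute ``attribute`` >= ``threshold``)."""

    attribute: int
    threshold: float


@dataclass(frozen=True)
class PairRule:
    """Label = (value of ``attribute1`` < value of ``attribute2``)."""

    attribute1: int
    attribute2: int


@dataclass(frozen=True)
class WeightedPairRule:
    """Label = (value of ``attribute1`` < weight * value of ``attribute2``)."""

    attribute1: int
    attribute2: int
    weight: float


PlantedRule = Union[ThresholdRule, PairRule, WeightedPairRule]


@dataclass(frozen=True)
class PlantedRuleSpec:
    """Recipe for one synthetic dataset.

    Defaults describe the standard recovery setting used throughout the
    test-bench: 200 samples, 50 log-normal(0, 1) attributes, no label noise.
    """

    rule: PlantedRule
    n_samples: int = 200
    n_attributes: int = 50
    noise_rate: float = 0.0
    log_mean: float = 0.0
    log_sigma: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 4:
            raise InputError("n_samples must be at least 4")
        pair = isinstance(self.rule, (PairRule, WeightedPairRule))
        if self.n_attributes < (2 if pair else 1):
            raise InputError("too few attributes for the planted rule")
        if not (0 <= self.noise_rate < 0.5):
            raise InputError("noise_rate must lie in [0, 0.5)")
        if self.log_sigma <= 0:
            raise InputError("log_sigma must be positive")
        idxs = (
            (self.rule.attribute1, self.rule.attribute2)
            if pair
            else (self.rule.attribute,)
        )
        if len(set(idxs)) != len(idxs):
            raise InputError("planted rule attributes must be distinct")
        for i in idxs:
            if not 0 <= i < self.n_attributes:
                raise InputError(f"rule attribute index {i} out of range")
        if isinstance(self.rule, WeightedPairRule) and not self.rule.weight > 0:
            raise InputError("planted weight must be positive")


def _attr_name(i: int) -> str:
    return f"g{i}"


def generate(spec: PlantedRuleSpec) -> Dataset:
    """Draw a dataset according to ``spec``.

    Values are i.i.d. log-normal (strictly positive, so WTSP ratio searches
    are always applicable); the class is the planted predicate, then flipped
    with probability ``noise_rate``.  Class levels are ``["pos", "neg"]``.
    """
    rng = np.random.default_rng(spec.seed)
    X = rng.lognormal(
        mean=spec.log_mean, sigma=spec.log_sigma,
        size=(spec.n_samples, spec.n_attributes),
    )
    r = spec.rule
    if isinstance(r, ThresholdRule):
        truth = X[:, r.attribute] >= r.threshold
    elif isinstance(r, PairRule):
        truth = X[:, r.attribute1] < X[:, r.attribute2]
    else:
        truth = X[:, r.attribute1] < r.weight * X[:, r.attribute2]
    if spec.noise_rate > 0:
        flips = rng.random(spec.n_samples) < spec.noise_rate
        truth = truth ^ flips
    labels = np.where(truth, 0, 1).astype(np.int64)  # pos = 0, neg = 1
    names = [_attr_name(i) for i in range(spec.n_attributes)]
    values = pd.DataFrame(X, columns=names)
    attrs = [AttributeMeta(nm, CONTINUOUS, i) for i, nm in enumerate(names)]
    ids = [f"s{i:04d}" for i in range(spec.n_samples)]
    return Dataset(attrs, "class", [POSITIVE, NEGATIVE], values, labels, ids)


def generate_nominal_block(
    n: int,
    categories: list[str],
    class_association: dict[str, dict[str, float]],
    seed: int = 0,
    attribute_name: str = "group",
) -> Dataset:
    """One nominal column whose category→class conditional distribution is
    ``class_association`` (map category -> map class label -> probability;
    each row must sum to 1).  Categories are drawn uniformly.
    """
    if len(categories) < 2:
        raise InputError("need at least two categories")
    class_levels: list[str] = []
    for cat in categories:
        if cat not in class_association:
            raise InputError(f"no class distribution for category {cat!r}")
        dist = class_association[cat]
        if abs(sum(dist.values()) - 1.0) > 1e-9:
            raise InputError(f"distribution for {cat!r} does not sum to 1")
        for lvl in dist:
            if lvl not in class_levels:
                class_levels.append(lvl)
    rng = np.random.default_rng(seed)
    cats = [categories[i] for i in rng.integers(0, len(categories), size=n)]
    labels = np.empty(n, dtype=np.int64)
    for i, cat in enumerate(cats):
        dist = class_association[cat]
        probs = np.array([dist.get(lvl, 0.0) for lvl in class_levels])
        labels[i] = rng.choice(len(class_levels), p=probs / probs.sum())
    values = pd.DataFrame({attribute_name: np.array(cats, dtype=object)})
    seen: list[str] = []
    for c in cats:
        if c not in seen:
            seen.append(c)
    attrs = [AttributeMeta(attribute_name, NOMINAL, 0, categories=tuple(seen))]
    ids = [f"s{i:04d}" for i in range(n)]
    return Dataset(attrs, "class", class_levels, values, labels, ids)
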