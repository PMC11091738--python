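"""Shared fixtures: hand-sized datasets and a random-dataset factory used
by the oracle-equivalence and invariant suites."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from mixtree.dataset import CONTINUOUS, NOMINAL, AttributeMeta, Dataset


def make_dataset(columns: dict, labels, class_levels=("A", "B"), ignore=()):
    """Build a Dataset from plain dicts: numeric lists become continuous
    attributes, string lists nominal ones."""
    attrs = []
    vals = {}
    for i, (name, col) in enumerate(columns.items()):
        if all(isinstance(v, (int, float)) for v in col):
            attrs.append(AttributeMeta(name, CONTINUOUS, i, name in ignore))
            vals[name] = np.asarray(col, dtype=np.float64)
        else:
            seen = []
            for v in col:
                if v not in seen:
                    seen.append(v)
            attrs.append(
                AttributeMeta(name, NOMINAL, i, name in ignore, tuple(seen))
            )
            vals[name] = np.asarray(col, dtype=object)
    return Dataset(
        attrs,
        "class",
        list(class_levels),
        pd.DataFrame(vals, columns=list(columns)),
        np.asarray(labels, dtype=np.int64),
    )


def random_dataset(seed: int, max_n: int = 30, max_p: int = 6,
                   allow_nominal: bool = True) -> Dataset:
    """Small random dataset for oracle comparisons: log-normal continuous
    columns (occasionally rounded to force ties, occasionally with a zero),
    sometimes one nominal column, 2 or 3 classes."""
    rng = np.random.default_rng(seed)
    n = int(rng.integers(5, max_n + 1))
    p = int(rng.integers(2, max_p + 1))
    n_classes = int(rng.integers(2, 4))
    cols = {}
    for j in range(p):
        v = rng.lognormal(0.0, 1.0, size=n)
        if rng.random() < 0.3:
            v = np.round(v, 1)  # duplicated values exercise tie handling
        if rng.random() < 0.15:
            v[rng.integers(0, n)] = 0.0  # disables this column as a WTSP denominator
        cols[f"g{j}"] = list(map(float, v))
    if allow_nominal and rng.random() < 0.4:
        cats = ["red", "blue", "green"][: int(rng.integers(2, 4))]
        cols["color"] = [cats[i] for i in rng.integers(0, len(cats), size=n)]
    labels = rng.integers(0, n_classes, size=n)
    # ensure every class level is represented
    labels[: n_classes] = np.arange(n_classes)
    return make_dataset(cols, labels, [f"c{k}" for k in range(n_classes)])


@pytest.fixture
def tsp_toy():
    """4 samples over 3 attributes where g1 < g2 separates the classes
    perfectly (and no other ordered pair does)."""
    return make_dataset(
        {"g1": [1, 2, 3, 5], "g2": [2, 3, 1, 2], "g3": [5, 1, 4, 2]},
        [0, 0, 1, 1],
        ("+", "-"),
    )


@pytest.fixture
def threshold_toy():
    """Classic threshold fixture: 1,2 class A; 5,6 class B -> cut at 3.5."""
    return make_dataset({"g1": [1, 2, 5, 6], "g2": [7, 7, 7, 7]}, [0, 0, 1, 1])


@pytest.fixture
def nominal_toy():
    """red,red class A; blue,green class B -> '== red' is a perfect split."""
    return make_dataset(
        {"color": ["red", "red", "blue", "green"]}, [0, 0, 1, 1]
    )
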