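"""CSV datasets: loading, typing, validation.

A dataset is a samples x attributes table with one designated class column.
Attributes are typed at load time: a column is *continuous* iff every cell
parses as a finite real, otherwise *nominal* (explicit overrides win, which
lets integer-coded categories be forced nominal).  Missing or unparseable
cells are a hard error — silent imputation would change split statistics
invisibly.

Class levels are ordered by first appearance in the training file; this
ordering fixes confusion-matrix layout and tie-breaking everywhere
downstream.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DataError, FormatError, InputError

CONTINUOUS = "continuous"
NOMINAL = "nominal"


@dataclass(frozen=True)
class AttributeMeta:
    """Per-attribute metadata.

    ``categories`` records the category set seen at load time for nominal
    attributes (ordered by first appearance); ``None`` for continuous ones.
    Ignored attributes stay in the table but are excluded from every split
    search.
    """

    name: str
    kind: str  # CONTINUOUS or NOMINAL
    index: int
    ignored: bool = False
    categories: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if self.kind not in (CONTINUOUS, NOMINAL):
            raise ValueError(f"unknown attribute kind {self.kind!r}")


@dataclass
class Dataset:
    """In-memory dataset: typed attribute columns plus an integer-coded label vector.

    ``values`` holds one column per attribute in schema order (float64 for
    continuous, str for nominal); ``labels[i]`` indexes into ``class_levels``.
    """

    attributes: list[AttributeMeta]
    class_name: str
    class_levels: list[str]
    values: pd.DataFrame
    labels: np.ndarray
    sample_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.values) < 1:
            raise InputError("dataset must contain at least one sample")
        if not self.sample_ids:
            self.sample_ids = [str(i) for i in range(len(self.values))]
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise FormatError("sample_ids must be unique")
        names = [a.name for a in self.attributes]
        if len(set(names)) != len(names):
            raise FormatError("attribute names must be unique")
        if self.class_name in names:
            raise ConfigurationError(
                f"class column {self.class_name!r} must not appear among attributes"
            )
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if self.labels.min(initial=0) < 0 or (
            len(self.labels) and self.labels.max() >= len(self.class_levels)
        ):
            raise DataError("label index out of range of class_levels")

    # -- basic accessors ---------------------------------------------------

    @property
    def n_samples(self) -> int:
        return len(self.values)

    @property
    def n_classes(self) -> int:
        return len(self.class_levels)

    def attribute(self, name: str) -> AttributeMeta:
        for a in self.attributes:
            if a.name == name:
                return a
        raise KeyError(name)

    def active_attributes(self, kind: str | None = None) -> list[AttributeMeta]:
        """Non-ignored attributes, optionally filtered by kind."""
        out = [a for a in self.attributes if not a.ignored]
        if kind is not None:
            out = [a for a in out if a.kind == kind]
        return out

    def column(self, name: str) -> np.ndarray:
        return self.values[name].to_numpy()

    def continuous_matrix(self, names: list[str]) -> np.ndarray:
        return self.values[list(names)].to_numpy(dtype=np.float64)

    def row(self, i: int) -> dict:
        return dict(self.values.iloc[i])

    def class_counts(self, rows: np.ndarray | None = None) -> np.ndarray:
        lab = self.labels if rows is None else self.labels[rows]
        return np.bincount(lab, minlength=self.n_classes).astype(np.int64)

    # -- I/O ---------------------------------------------------------------

    def to_csv(self, path) -> None:
        """Write attributes plus the class column back to RFC 4180 CSV."""
        out = self.values.copy()
        out[self.class_name] = [self.class_levels[i] for i in self.labels]
        out.to_csv(path, index=False)


def _parse_float(cell: str) -> float | None:
    try:
        v = float(cell)
    except (TypeError, ValueError):
        return None
    return v if math.isfinite(v) else None


def _read_raw(path) -> pd.DataFrame:
    try:
        raw = pd.read_csv(path, dtype=str, keep_default_na=False, skipinitialspace=True)
    except FileNotFoundError:
        raise
    except Exception as exc:  # malformed CSV structure
        raise FormatError(f"cannot parse CSV {path}: {exc}") from exc
    cols = list(raw.columns)
    dupes = {c for c in cols if cols.count(c) > 1}
    # pandas mangles duplicate headers to name.1, name.2, ...; detect both forms
    mangled = {c.rsplit(".", 1)[0] for c in cols if c.rsplit(".", 1)[-1].isdigit()}
    dupes |= {m for m in mangled if m in cols}
    if dupes:
        raise FormatError(f"duplicate header names in {path}: {sorted(dupes)}")
    return raw


def read_csv_dataset(
    path,
    class_column: str,
    ignore: list[str] | None = None,
    type_overrides: dict[str, str] | None = None,
) -> Dataset:
    """Load a training dataset from CSV.

    Parameters
    ----------
    path
        CSV file with a header row (comma separator, RFC 4180 quoting).
    class_column
        Name of the class (decision) column.
    ignore
        Attribute names to flag as ignored; they are retained in the table
        but excluded from every split search.
    type_overrides
        Map attribute name -> ``"continuous"``/``"nominal"`` forcing the type.

    Raises
    ------
    ConfigurationError
        ``class_column`` or an ``ignore``/override name is absent from the header.
    FormatError
        duplicate header names or unreadable CSV.
    DataError
        an empty or unparseable cell under its resolved type (row and column
        are named; missing values are rejected, never imputed).
    """
    ignore = list(ignore or [])
    type_overrides = dict(type_overrides or {})
    raw = _read_raw(path)
    if class_column not in raw.columns:
        raise ConfigurationError(
            f"class column {class_column!r} not found in header of {path}"
        )
    for name in ignore:
        if name not in raw.columns:
            raise ConfigurationError(f"ignored attribute {name!r} not in header")
    for name, kind in type_overrides.items():
        if name not in raw.columns:
            raise ConfigurationError(f"type override for unknown attribute {name!r}")
        if kind not in (CONTINUOUS, NOMINAL):
            raise ConfigurationError(f"unknown type override {kind!r} for {name!r}")

    attr_names = [c for c in raw.columns if c != class_column]
    attrs: list[AttributeMeta] = []
    cols: dict[str, object] = {}
    for idx, name in enumerate(attr_names):
        cells = raw[name].tolist()
        for r, cell in enumerate(cells):
            if cell == "":
                raise DataError(f"empty cell at row {r}, column {name!r}")
        parsed = [_parse_float(c) for c in cells]
        inferred = CONTINUOUS if all(v is not None for v in parsed) else NOMINAL
        kind = type_overrides.get(name, inferred)
        if kind == CONTINUOUS:
            for r, v in enumerate(parsed):
                if v is None:
                    raise DataError(
                        f"cell at row {r}, column {name!r} is not a finite number: "
                        f"{cells[r]!r}"
                    )
            cols[name] = np.array(parsed, dtype=np.float64)
            attrs.append(AttributeMeta(name, CONTINUOUS, idx, name in ignore))
        else:
            seen: list[str] = []
            for c in cells:
                if c not in seen:
                    seen.append(c)
            cols[name] = np.array(cells, dtype=object)
            attrs.append(
                AttributeMeta(name, NOMINAL, idx, name in ignore, tuple(seen))
            )

    class_cells = raw[class_column].tolist()
    for r, cell in enumerate(class_cells):
        if cell == "":
            raise DataError(f"empty cell at row {r}, column {class_column!r}")
    levels: list[str] = []
    for c in class_cells:
        if c not in levels:
            levels.append(c)
    labels = np.array([levels.index(c) for c in class_cells], dtype=np.int64)
    values = pd.DataFrame(cols, columns=attr_names)
    return Dataset(attrs, class_column, levels, values, labels)


def align_test_set(train: Dataset, path) -> Dataset:
    """Load a test CSV and align it to a training dataset's schema.

    Columns may appear in any order; they are realigned to the training
    order and coerced to the training types.  A nominal value unseen in
    training is kept verbatim as a distinct out-of-vocabulary category
    (category tests route such rows to the non-matching side).  A class
    label unseen in training is appended after the training levels.
    """
    raw = _read_raw(path)
    if train.class_name not in raw.columns:
        raise FormatError(f"test file missing class column {train.class_name!r}")
    cols: dict[str, object] = {}
    for a in train.attributes:
        if a.name not in raw.columns:
            raise FormatError(f"test file missing attribute column {a.name!r}")
        cells = raw[a.name].tolist()
        for r, cell in enumerate(cells):
            if cell == "":
                raise DataError(f"empty cell at row {r}, column {a.name!r}")
        if a.kind == CONTINUOUS:
            parsed = [_parse_float(c) for c in cells]
            for r, v in enumerate(parsed):
                if v is None:
                    raise DataError(
                        f"cell at row {r}, column {a.name!r} is not a finite "
                        f"number: {cells[r]!r}"
                    )
            cols[a.name] = np.array(parsed, dtype=np.float64)
        else:
            cols[a.name] = np.array(cells, dtype=object)

    levels = list(train.class_levels)
    class_cells = raw[train.class_name].tolist()
    for r, cell in enumerate(class_cells):
        if cell == "":
            raise DataError(f"empty cell at row {r}, column {train.class_name!r}")
    for c in class_cells:
        if c not in levels:
            levels.append(c)
    labels = np.array([levels.index(c) for c in class_cells], dtype=np.int64)
    values = pd.DataFrame(cols, columns=[a.name for a in train.attributes])
    return Dataset(
        [replace(a) for a in train.attributes],
        train.class_name,
        levels,
        values,
        labels,
    )
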