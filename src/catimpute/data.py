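"""Typed categorical tables, schema handling, CSV I/O and the one-hot codec.

The in-memory container is :class:`DiscreteTable`: a fixed schema of
categorical (and optionally numeric) attributes plus a column store of
integer category codes.  Missing categorical cells are coded ``-1``; missing
numeric cells are ``NaN``.  The canonical category order is the order the
schema declares a domain in — it fixes one-hot positions and every
tie-break in the package.

A table splits into the complete-row part ``Dcom`` (no missing cell) and the
incomplete part ``Dmiss``; the distinct patterns of simultaneously-missing
attributes among ``Dmiss`` rows are the table's *missing types*.
"""

from __future__ import annotations

import csv
import json
import os
import tempfile
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .errors import (
    ConfigError,
    CsvParseError,
    LayoutMismatchError,
    MissingCellError,
    SchemaViolationError,
)

DEFAULT_SENTINEL = "?"


class _MissingType:
    """Singleton sentinel for a missing cell value."""

    _instance = None

    def __new__(cls):
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return "MISSING"


#: Sentinel object returned by :meth:`DiscreteTable.cell` for missing cells.
MISSING = _MissingType()


# ---------------------------------------------------------------------------
# Schema
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Attribute:
    """One column of a table: a name, a kind, a domain and a role.

    ``domain`` is the ordered tuple of category labels for categorical
    attributes (``None`` for numeric ones).  ``role`` is ``"feature"`` or
    ``"class"``; at most one attribute of a schema may be the class.
    """

    name: str
    kind: str = "categorical"
    domain: tuple[str, ...] | None = None
    role: str = "feature"

    def __post_init__(self) -> None:
        if not self.name:
            raise ConfigError("attribute name must be non-empty")
        if self.kind not in ("categorical", "numeric"):
            raise ConfigError(f"unknown attribute kind {self.kind!r}")
        if self.role not in ("feature", "class"):
            raise ConfigError(f"unknown attribute role {self.role!r}")
        if self.kind == "categorical":
            if not self.domain:
                raise ConfigError(f"attribute {self.name!r}: empty domain")
            if len(set(self.domain)) != len(self.domain):
                raise ConfigError(f"attribute {self.name!r}: duplicate domain labels")
            object.__setattr__(self, "domain", tuple(str(v) for v in self.domain))
        else:
            if self.domain is not None:
                raise ConfigError(f"numeric attribute {self.name!r} must not declare a domain")
            if self.role == "class":
                raise ConfigError("class attribute must be categorical")


class CategoricalSchema:
    """Ordered attribute list with at most one class column."""

    def __init__(self, attributes: Sequence[Attribute]):
        attrs = tuple(attributes)
        names = [a.name for a in attrs]
        if len(set(names)) != len(names):
            raise ConfigError("attribute names must be unique")
        n_class = sum(1 for a in attrs if a.role == "class")
        if n_class > 1:
            raise ConfigError("at most one attribute may have role=class")
        self.attributes: tuple[Attribute, ...] = attrs

    # -- basic accessors ----------------------------------------------------
    @property
    def n_attrs(self) -> int:
        return len(self.attributes)

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(a.name for a in self.attributes)

    @property
    def class_index(self) -> int | None:
        for j, a in enumerate(self.attributes):
            if a.role == "class":
                return j
        return None

    @property
    def categorical_indices(self) -> tuple[int, ...]:
        return tuple(j for j, a in enumerate(self.attributes) if a.kind == "categorical")

    @property
    def feature_indices(self) -> tuple[int, ...]:
        return tuple(j for j, a in enumerate(self.attributes) if a.role == "feature")

    @property
    def eligible_indices(self) -> tuple[int, ...]:
        """Attributes that may be amputed/imputed: categorical features."""
        return tuple(
            j for j, a in enumerate(self.attributes)
            if a.kind == "categorical" and a.role == "feature"
        )

    def index_of(self, name: str) -> int:
        try:
            return self.names.index(name)
        except ValueError:
            raise ConfigError(f"no attribute named {name!r}") from None

    def domain(self, j: int) -> tuple[str, ...]:
        dom = self.attributes[j].domain
        if dom is None:
            raise ConfigError(f"attribute {self.attributes[j].name!r} is numeric")
        return dom

    def __eq__(self, other: object) -> bool:
        return isinstance(other, CategoricalSchema) and self.attributes == other.attributes

    def __hash__(self) -> int:
        return hash(self.attributes)

    # -- JSON serialization -------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "attributes": [
                {
                    "name": a.name,
                    "kind": a.kind,
                    **({"domain": list(a.domain)} if a.domain is not None else {}),
                    "role": a.role,
                }
                for a in self.attributes
            ]
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CategoricalSchema":
        attrs = [
            Attribute(
                name=a["name"],
                kind=a.get("kind", "categorical"),
                domain=tuple(a["domain"]) if a.get("domain") is not None else None,
                role=a.get("role", "feature"),
            )
            for a in d["attributes"]
        ]
        return cls(attrs)

    def save(self, path: str) -> None:
        _atomic_write_text(path, json.dumps(self.to_dict(), indent=2) + "\n")

    @classmethod
    def load(cls, path: str) -> "CategoricalSchema":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


# ---------------------------------------------------------------------------
# Table
# ---------------------------------------------------------------------------

class DiscreteTable:
    """Rows x attributes of category codes with an explicit missing mask.

    Columns are numpy arrays: ``int32`` category codes for categorical
    attributes (``-1`` = missing), ``float64`` for numeric ones (``NaN`` =
    missing).  ``row_ids`` preserves original row identities across
    splitting and reconstruction.
    """

    def __init__(
        self,
        schema: CategoricalSchema,
        columns: Sequence[np.ndarray],
        row_ids: np.ndarray | None = None,
    ):
        if len(columns) != schema.n_attrs:
            raise ConfigError(
                f"expected {schema.n_attrs} columns, got {len(columns)}"
            )
        cols: list[np.ndarray] = []
        n_rows = len(columns[0]) if columns else 0
        for j, (attr, col) in enumerate(zip(schema.attributes, columns)):
            arr = np.asarray(col)
            if len(arr) != n_rows:
                raise ConfigError("columns have unequal lengths")
            if attr.kind == "categorical":
                arr = arr.astype(np.int32, copy=True)
                dom_size = len(attr.domain)  # type: ignore[arg-type]
                bad = (arr < -1) | (arr >= dom_size)
                if bad.any():
                    r = int(np.nonzero(bad)[0][0])
                    raise SchemaViolationError(
                        f"code {arr[r]} out of range for attribute "
                        f"{attr.name!r} (column {j + 1}) at row {r + 1}"
                    )
                if attr.role == "class" and (arr < 0).any():
                    r = int(np.nonzero(arr < 0)[0][0])
                    raise SchemaViolationError(
                        f"class column {attr.name!r} has a missing cell at row {r + 1}"
                    )
            else:
                arr = arr.astype(np.float64, copy=True)
            cols.append(arr)
        self.schema = schema
        self.columns: list[np.ndarray] = cols
        if row_ids is None:
            row_ids = np.arange(n_rows, dtype=np.int64)
        else:
            row_ids = np.asarray(row_ids, dtype=np.int64).copy()
            if len(row_ids) != n_rows:
                raise ConfigError("row_ids length mismatch")
        self.row_ids: np.ndarray = row_ids

    # -- construction helpers ----------------------------------------------
    @classmethod
    def from_labels(
        cls,
        schema: CategoricalSchema,
        rows: Iterable[Sequence[object]],
        missing_sentinel: str = DEFAULT_SENTINEL,
    ) -> "DiscreteTable":
        """Build a table from rows of labels (strings / floats / MISSING)."""
        rows = [list(r) for r in rows]
        n = len(rows)
        cols: list[np.ndarray] = []
        for j, attr in enumerate(schema.attributes):
            if attr.kind == "categorical":
                lookup = {lab: c for c, lab in enumerate(attr.domain)}  # type: ignore[arg-type]
                arr = np.empty(n, dtype=np.int32)
                for r, row in enumerate(rows):
                    v = row[j]
                    if v is MISSING or v == missing_sentinel:
                        arr[r] = -1
                    else:
                        try:
                            arr[r] = lookup[str(v)]
                        except KeyError:
                            raise SchemaViolationError(
                                f"value {v!r} not in domain of attribute "
                                f"{attr.name!r} (column {j + 1}) at row {r + 1}"
                            ) from None
            else:
                arr = np.empty(n, dtype=np.float64)
                for r, row in enumerate(rows):
                    v = row[j]
                    if v is MISSING or v == missing_sentinel:
                        arr[r] = np.nan
                    else:
                        try:
                            arr[r] = float(v)  # type: ignore[arg-type]
                        except (TypeError, ValueError):
                            raise SchemaViolationError(
                                f"non-numeric value {v!r} in numeric attribute "
                                f"{attr.name!r} (column {j + 1}) at row {r + 1}"
                            ) from None
            cols.append(arr)
        return cls(schema, cols)

    # -- accessors ----------------------------------------------------------
    @property
    def n_rows(self) -> int:
        return len(self.columns[0]) if self.columns else 0

    def cell(self, r: int, j: int):
        """Return the label (str), numeric value (float) or MISSING at (r, j)."""
        attr = self.schema.attributes[j]
        v = self.columns[j][r]
        if attr.kind == "categorical":
            return MISSING if v < 0 else attr.domain[int(v)]  # type: ignore[index]
        return MISSING if np.isnan(v) else float(v)

    @property
    def missing_mask(self) -> np.ndarray:
        """Boolean (n_rows, n_attrs) matrix, True where a cell is MISSING."""
        cols = []
        for attr, col in zip(self.schema.attributes, self.columns):
            cols.append(col < 0 if attr.kind == "categorical" else np.isnan(col))
        return np.column_stack(cols) if cols else np.zeros((0, 0), dtype=bool)

    @property
    def is_complete(self) -> bool:
        return not self.missing_mask.any()

    def copy(self) -> "DiscreteTable":
        return DiscreteTable(self.schema, [c.copy() for c in self.columns], self.row_ids)

    def take(self, rows: np.ndarray) -> "DiscreteTable":
        rows = np.asarray(rows, dtype=np.int64)
        return DiscreteTable(
            self.schema, [c[rows] for c in self.columns], self.row_ids[rows]
        )

    def equals(self, other: "DiscreteTable") -> bool:
        """Cell-for-cell equality (schema, codes, missingness and row ids)."""
        if self.schema != other.schema or self.n_rows != other.n_rows:
            return False
        if not np.array_equal(self.row_ids, other.row_ids):
            return False
        for attr, a, b in zip(self.schema.attributes, self.columns, other.columns):
            if attr.kind == "categorical":
                if not np.array_equal(a, b):
                    return False
            else:
                if not np.array_equal(np.isnan(a), np.isnan(b)):
                    return False
                ok = np.isnan(a) | (a == b)
                if not ok.all():
                    return False
        return True


# ---------------------------------------------------------------------------
# Missing types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MissingType:
    """A distinct pattern of simultaneously-missing attribute indices.

    ``rows`` lists the positions (within the table the type was detected on)
    of every row exhibiting exactly this pattern.
    """

    missing_attrs: tuple[int, ...]
    rows: tuple[int, ...]

    def __post_init__(self) -> None:
        if not self.missing_attrs:
            raise ConfigError("a missing type must have at least one missing attribute")


def detect_missing_types(table: DiscreteTable) -> list[MissingType]:
    """Group incomplete rows by their exact set of missing attributes.

    Returns one :class:`MissingType` per distinct pattern, sorted
    lexicographically by the missing-attribute index tuple; the row lists
    partition the incomplete rows exactly.
    """
    mask = table.missing_mask
    groups: dict[tuple[int, ...], list[int]] = {}
    for r in np.nonzero(mask.any(axis=1))[0]:
        key = tuple(int(j) for j in np.nonzero(mask[r])[0])
        groups.setdefault(key, []).append(int(r))
    return [
        MissingType(missing_attrs=key, rows=tuple(rows))
        for key, rows in sorted(groups.items())
    ]


def split_by_completeness(table: DiscreteTable) -> tuple[DiscreteTable, DiscreteTable]:
    """Partition into (Dcom, Dmiss): rows with no missing cell vs the rest."""
    any_missing = table.missing_mask.any(axis=1)
    return table.take(np.nonzero(~any_missing)[0]), table.take(np.nonzero(any_missing)[0])


# ---------------------------------------------------------------------------
# One-hot codec
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class _Block:
    attr: int
    offset: int
    width: int
    lo: float = 0.0  # numeric min-max bounds (from complete rows)
    hi: float = 1.0


class OneHotLayout:
    """Contiguous one-hot block layout over a subset of attributes.

    Categorical attributes get ``|domain|`` indicator positions in domain
    order; numeric attributes get one position, min-max scaled to [0, 1]
    with bounds taken from the complete rows of the table the layout was
    built on (out-of-range values clip).
    """

    def __init__(self, schema: CategoricalSchema, blocks: Sequence[_Block]):
        self.schema = schema
        self.blocks: tuple[_Block, ...] = tuple(blocks)
        self.total_width = sum(b.width for b in self.blocks)
        self._by_attr = {b.attr: b for b in self.blocks}

    @property
    def attrs(self) -> tuple[int, ...]:
        return tuple(b.attr for b in self.blocks)

    def block_for(self, attr: int) -> _Block:
        return self._by_attr[attr]

    @classmethod
    def from_table(
        cls, table: DiscreteTable, attrs: Sequence[int] | None = None
    ) -> "OneHotLayout":
        schema = table.schema
        if attrs is None:
            attrs = range(schema.n_attrs)
        attrs = sorted(int(j) for j in attrs)
        complete = ~table.missing_mask.any(axis=1)
        blocks: list[_Block] = []
        offset = 0
        for j in attrs:
            attr = schema.attributes[j]
            if attr.kind == "categorical":
                width = len(attr.domain)  # type: ignore[arg-type]
                blocks.append(_Block(attr=j, offset=offset, width=width))
            else:
                vals = table.columns[j][complete]
                vals = vals[~np.isnan(vals)]
                lo = float(vals.min()) if vals.size else 0.0
                hi = float(vals.max()) if vals.size else 1.0
                blocks.append(_Block(attr=j, offset=offset, width=1, lo=lo, hi=hi))
                width = 1
            offset += width
        return cls(schema, blocks)


def encode_one_hot(
    table: DiscreteTable,
    layout: OneHotLayout,
    rows: Sequence[int] | np.ndarray | None = None,
) -> np.ndarray:
    """Encode the layout's attributes for the given rows as a float matrix.

    Every encoded cell must be observed; hit a MISSING cell and a
    :class:`MissingCellError` identifies it (prefill first if needed).
    """
    if rows is None:
        rows = np.arange(table.n_rows)
    rows = np.asarray(rows, dtype=np.int64)
    out = np.zeros((len(rows), layout.total_width), dtype=np.float64)
    for b in layout.blocks:
        attr = table.schema.attributes[b.attr]
        col = table.columns[b.attr][rows]
        if attr.kind == "categorical":
            if (col < 0).any():
                r = int(rows[np.nonzero(col < 0)[0][0]])
                raise MissingCellError(
                    f"cannot encode MISSING cell at row {r + 1}, "
                    f"attribute {attr.name!r} (column {b.attr + 1})"
                )
            out[np.arange(len(rows)), b.offset + col.astype(np.int64)] = 1.0
        else:
            if np.isnan(col).any():
                r = int(rows[np.nonzero(np.isnan(col))[0][0]])
                raise MissingCellError(
                    f"cannot encode MISSING cell at row {r + 1}, "
                    f"attribute {attr.name!r} (column {b.attr + 1})"
                )
            span = b.hi - b.lo
            scaled = np.full_like(col, 0.5) if span == 0 else (col - b.lo) / span
            out[:, b.offset] = np.clip(scaled, 0.0, 1.0)
    return out


def _decode_codes(
    scores: np.ndarray, layout: OneHotLayout, attrs: Sequence[int]
) -> dict[int, np.ndarray]:
    """Per-attribute argmax codes from a score matrix over the given blocks.

    ``scores`` columns are the concatenated blocks of ``attrs`` in ascending
    attribute order.  Ties break to the lowest domain index.
    """
    attrs = sorted(int(j) for j in attrs)
    widths = [layout.block_for(j).width for j in attrs]
    if scores.ndim != 2 or scores.shape[1] != sum(widths):
        raise LayoutMismatchError(
            f"score width {scores.shape[1] if scores.ndim == 2 else scores.shape} "
            f"does not match layout width {sum(widths)}"
        )
    out: dict[int, np.ndarray] = {}
    offset = 0
    for j, w in zip(attrs, widths):
        block = scores[:, offset:offset + w]
        out[j] = block.argmax(axis=1).astype(np.int32)
        offset += w
    return out


def decode_one_hot(
    scores: np.ndarray, layout: OneHotLayout, attrs: Sequence[int]
) -> dict[int, list[str]]:
    """Decode score blocks back to category labels, attribute by attribute."""
    codes = _decode_codes(scores, layout, attrs)
    return {
        j: [layout.schema.domain(j)[int(c)] for c in arr] for j, arr in codes.items()
    }


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------

def _atomic_write_text(path: str, text: str) -> None:
    """Write text to ``path`` via a same-directory temp file + rename."""
    d = os.path.dirname(os.path.abspath(path))
    fd, tmp = tempfile.mkstemp(dir=d, suffix=".tmp")
    try:
        with os.fdopen(fd, "w", newline="") as fh:
            fh.write(text)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def infer_schema(
    header: Sequence[str],
    rows: Sequence[Sequence[str]],
    missing_sentinel: str = DEFAULT_SENTINEL,
) -> CategoricalSchema:
    """Infer an all-categorical schema from raw CSV cells.

    Each column's domain is the lexicographically sorted set of observed
    values; the last column becomes the class (it must be fully observed).
    """
    attrs = []
    for j, name in enumerate(header):
        observed = sorted({row[j] for row in rows if row[j] != missing_sentinel})
        if not observed:
            raise SchemaViolationError(
                f"column {name!r} has no observed values; cannot infer a domain"
            )
        role = "class" if j == len(header) - 1 else "feature"
        attrs.append(Attribute(name=name, domain=tuple(observed), role=role))
    return CategoricalSchema(attrs)


def read_table(
    path: str,
    schema: CategoricalSchema | None = None,
    missing_sentinel: str = DEFAULT_SENTINEL,
) -> DiscreteTable:
    """Read a header-rowed CSV into a :class:`DiscreteTable`.

    Sentinel cells (default ``"?"``, the UCI convention) become MISSING.
    With no schema given, one is inferred: every column categorical with the
    sorted observed values as its domain, last column as the class.
    """
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise CsvParseError(f"{path}: empty file, expected a header row") from None
        rows = []
        for i, row in enumerate(reader):
            if len(row) != len(header):
                raise CsvParseError(
                    f"{path}: row {i + 2} has {len(row)} fields, expected {len(header)}"
                )
            rows.append(row)
    if schema is None:
        schema = infer_schema(header, rows, missing_sentinel)
    else:
        if list(header) != list(schema.names):
            raise SchemaViolationError(
                f"{path}: header {header!r} does not match schema attributes "
                f"{list(schema.names)!r}"
            )
    return DiscreteTable.from_labels(schema, rows, missing_sentinel)


def write_table(
    table: DiscreteTable, path: str, missing_sentinel: str = DEFAULT_SENTINEL
) -> None:
    """Write a table as CSV so that :func:`read_table` round-trips it.

    Missing cells serialize as the sentinel; the write is atomic (temp file
    plus rename), so no partial CSV is ever left behind.
    """
    import io

    buf = io.StringIO()
    writer = csv.writer(buf, lineterminator="\n")
    writer.writerow(table.schema.names)
    for r in range(table.n_rows):
        out_row = []
        for j, attr in enumerate(table.schema.attributes):
            v = table.cell(r, j)
            if v is MISSING:
                out_row.append(missing_sentinel)
            elif attr.kind == "numeric":
                out_row.append(repr(float(v)))
            else:
                out_row.append(v)
        writer.writerow(out_row)
    _atomic_write_text(path, buf.getvalue())
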