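"""Reading, writing and pair enumeration for binary presence/absence datasets.

A dataset is a formula × ingredient 0/1 matrix: rows are herbal-medicine
formulas (or any sample described by a binary fingerprint), columns are
ingredients (features), and an optional label map attaches one or more
efficacy-class codes to each formula.
"""

from __future__ import annotations

import csv
import io
import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "BinaryDataset",
    "DatasetParseError",
    "read_matrix",
    "write_matrix",
    "read_labels",
    "write_labels",
    "enumerate_pairs",
    "count_pairs",
]


class DatasetParseError(ValueError):
    """Raised for malformed matrix or label files; carries a line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


@dataclass
class BinaryDataset:
    """A formula × ingredient presence/absence matrix with optional labels.

    Parameters
    ----------
    formula_ids : ordered unique row identifiers.
    ingredient_ids : ordered unique column identifiers.
    matrix : (N, V) array with entries in {0, 1}.
    labels : optional map formula id -> nonempty frozenset of class codes.
    """

    formula_ids: list[str]
    ingredient_ids: list[str]
    matrix: np.ndarray
    labels: dict[str, frozenset[str]] | None = field(default=None)

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix)
        n, v = self.matrix.shape
        if len(self.formula_ids) != n:
            raise ValueError(
                f"{len(self.formula_ids)} formula ids for {n} matrix rows"
            )
        if len(self.ingredient_ids) != v:
            raise ValueError(
                f"{len(self.ingredient_ids)} ingredient ids for {v} matrix columns"
            )
        if len(set(self.formula_ids)) != n:
            raise ValueError("duplicate formula ids")
        if len(set(self.ingredient_ids)) != v:
            raise ValueError("duplicate ingredient ids")
        if not np.isin(self.matrix, (0, 1)).all():
            bad = self.matrix[~np.isin(self.matrix, (0, 1))].flat[0]
            raise ValueError(f"non-binary cell value {bad!r}")
        self.matrix = self.matrix.astype(np.int8, copy=False)
        zero_rows = np.flatnonzero(self.matrix.sum(axis=1) == 0)
        if zero_rows.size:
            warnings.warn(
                f"{zero_rows.size} all-zero formula row(s), e.g. "
                f"{self.formula_ids[zero_rows[0]]!r}",
                stacklevel=2,
            )
        if self.labels is not None:
            self._validate_labels(self.labels)

    def _validate_labels(self, labels: dict[str, frozenset[str]]) -> None:
        known = set(self.formula_ids)
        for fid, classes in labels.items():
            if fid not in known:
                raise KeyError(f"label for unknown formula {fid!r}")
            if not classes:
                raise ValueError(f"empty label set for formula {fid!r}")

    # -- convenience -------------------------------------------------------

    @property
    def n_formulas(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_ingredients(self) -> int:
        return self.matrix.shape[1]

    def label_sets(self) -> list[frozenset[str]]:
        """Per-row label sets in row order; raises if any row is unlabeled."""
        if self.labels is None:
            raise ValueError("dataset has no labels")
        out = []
        for fid in self.formula_ids:
            if fid not in self.labels:
                raise ValueError(f"formula {fid!r} has no efficacy label")
            out.append(self.labels[fid])
        return out

    def class_codes(self) -> set[str]:
        return set().union(*self.label_sets())

    def with_labels(self, labels: dict[str, frozenset[str]]) -> "BinaryDataset":
        return BinaryDataset(
            self.formula_ids, self.ingredient_ids, self.matrix, labels
        )


def _sniff_delimiter(sample: str) -> str:
    # auto-detect among comma/tab; comma wins on a tie-free sample
    header = sample.splitlines()[0] if sample else ""
    if header.count("\t") > header.count(","):
        return "\t"
    return ","


def read_matrix(path, delimiter: str | None = None) -> BinaryDataset:
    """Read a formula × ingredient matrix from delimited text.

    First row: header with ingredient ids (first field names the id column).
    Following rows: formula id then 0/1 cells.
    """
    with open(path, "r", encoding="utf-8", newline="") as fh:
        text = fh.read()
    if not text.strip():
        raise DatasetParseError("empty matrix file", line=1)
    if delimiter is None:
        delimiter = _sniff_delimiter(text)
    reader = csv.reader(io.StringIO(text), delimiter=delimiter)
    header = next(reader)
    ingredient_ids = [h.strip() for h in header[1:]]
    if not ingredient_ids:
        raise DatasetParseError("header has no ingredient columns", line=1)
    formula_ids: list[str] = []
    rows: list[list[int]] = []
    for lineno, rec in enumerate(reader, start=2):
        if not rec or (len(rec) == 1 and not rec[0].strip()):
            continue
        if len(rec) != len(header):
            raise DatasetParseError(
                f"expected {len(header)} fields, found {len(rec)}", line=lineno
            )
        formula_ids.append(rec[0].strip())
        row = []
        for cell in rec[1:]:
            cell = cell.strip()
            if cell not in ("0", "1"):
                raise DatasetParseError(
                    f"non-binary cell {cell!r}", line=lineno
                )
            row.append(int(cell))
        rows.append(row)
    if len(set(formula_ids)) != len(formula_ids):
        seen: set[str] = set()
        for lineno, fid in enumerate(formula_ids, start=2):
            if fid in seen:
                raise DatasetParseError(
                    f"duplicate formula id {fid!r}", line=lineno
                )
            seen.add(fid)
    if len(set(ingredient_ids)) != len(ingredient_ids):
        raise DatasetParseError("duplicate ingredient ids in header", line=1)
    return BinaryDataset(formula_ids, ingredient_ids, np.array(rows, dtype=np.int8))


def write_matrix(dataset: BinaryDataset, path, delimiter: str = ",") -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        writer = csv.writer(fh, delimiter=delimiter, lineterminator="\n")
        writer.writerow(["formula_id", *dataset.ingredient_ids])
        for fid, row in zip(dataset.formula_ids, dataset.matrix):
            writer.writerow([fid, *row.tolist()])


def read_labels(path, dataset: BinaryDataset | None = None,
                delimiter: str | None = None) -> dict[str, frozenset[str]]:
    """Read a two-column label file: formula id, ';'-separated class codes."""
    with open(path, "r", encoding="utf-8", newline="") as fh:
        text = fh.read()
    if delimiter is None:
        delimiter = _sniff_delimiter(text)
    labels: dict[str, frozenset[str]] = {}
    known = set(dataset.formula_ids) if dataset is not None else None
    reader = csv.reader(io.StringIO(text), delimiter=delimiter)
    for lineno, rec in enumerate(reader, start=1):
        if not rec or (len(rec) == 1 and not rec[0].strip()):
            continue
        if lineno == 1 and rec[0].strip().lower() in ("formula_id", "id"):
            continue
        if len(rec) < 2:
            raise DatasetParseError("expected formula id and class codes",
                                    line=lineno)
        fid = rec[0].strip()
        codes = frozenset(c.strip() for c in rec[1].split(";") if c.strip())
        if not codes:
            raise DatasetParseError(f"empty label field for {fid!r}",
                                    line=lineno)
        if known is not None and fid not in known:
            raise KeyError(f"label for formula {fid!r} absent from matrix")
        labels[fid] = codes
    return labels


def write_labels(labels: dict[str, frozenset[str]], path,
                 delimiter: str = ",") -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        writer = csv.writer(fh, delimiter=delimiter, lineterminator="\n")
        writer.writerow(["formula_id", "classes"])
        for fid, codes in labels.items():
            writer.writerow([fid, ";".join(sorted(codes))])


def count_pairs(n: int) -> int:
    """Closed-form number of unordered formula pairs, n(n-1)/2."""
    if n < 2:
        raise ValueError(f"need at least 2 formulas, got {n}")
    return n * (n - 1) // 2


def enumerate_pairs(dataset_or_n) -> tuple[np.ndarray, np.ndarray]:
    """Row-major upper-triangle pair indices (i, j) with i < j.

    Accepts a :class:`BinaryDataset` or a row count. The order is the
    deterministic total order (0,1), (0,2), ..., (0,n-1), (1,2), ...
    """
    if isinstance(dataset_or_n, BinaryDataset):
        n = dataset_or_n.n_formulas
    else:
        n = int(dataset_or_n)
    if n < 2:
        raise ValueError(f"need at least 2 formulas, got {n}")
    return np.triu_indices(n, k=1)
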