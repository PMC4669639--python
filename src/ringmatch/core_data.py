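"""Core domain types and tab-separated I/O for binary annotation matrices.

An annotation matrix records presence (1) / absence (0) of signature
features for a set of enzymes.  The on-disk layout is a TSV whose first
column carries the enzyme identifier, whose middle columns carry one
signature each, and whose last column carries the ";"-separated mechanism
labels of the enzyme.  Row and column order are significant and preserved
verbatim through I/O.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np

__all__ = [
    "MatrixFormatError",
    "AnnotationMatrix",
    "LabelAssignment",
    "ClassSizeTable",
    "Prediction",
    "read_matrix",
    "write_matrix",
    "parse_class_sizes",
    "load_class_size_fixture",
    "CLASS_SIZE_FIXTURE",
]

CLASS_SIZE_FIXTURE = "table1_class_sizes.tsv"

_LABEL_RE = re.compile(r"^M\d{4}$")


class MatrixFormatError(ValueError):
    """Raised when an on-disk matrix or fixture violates the expected layout."""


@dataclass(frozen=True)
class AnnotationMatrix:
    """Binary enzyme x signature matrix with ordered row/column identifiers.

    Parameters
    ----------
    row_ids:
        Ordered, unique enzyme identifiers.
    col_ids:
        Ordered, unique signature identifiers; length defines the feature
        dimension ``L`` (must be >= 1).
    cells:
        ``|row_ids| x |col_ids|`` array of 0/1 values.  Stored as ``uint8``.

    A zero-row matrix is permitted (it serialises to a header-only file);
    a zero-column matrix is not.
    """

    row_ids: tuple[str, ...]
    col_ids: tuple[str, ...]
    cells: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "row_ids", tuple(self.row_ids))
        object.__setattr__(self, "col_ids", tuple(self.col_ids))
        cells = np.asarray(self.cells)
        if cells.ndim != 2:
            raise MatrixFormatError("cells must be a 2-D array")
        if not np.isin(cells, (0, 1)).all():
            raise MatrixFormatError("cells must contain only 0 and 1")
        cells = cells.astype(np.uint8)
        cells.setflags(write=False)
        object.__setattr__(self, "cells", cells)
        if len(set(self.row_ids)) != len(self.row_ids):
            raise MatrixFormatError("duplicate row identifiers")
        if len(set(self.col_ids)) != len(self.col_ids):
            raise MatrixFormatError("duplicate column identifiers")
        if len(self.col_ids) < 1:
            raise MatrixFormatError("matrix must have at least one signature column")
        if cells.shape != (len(self.row_ids), len(self.col_ids)):
            raise MatrixFormatError(
                f"cells shape {cells.shape} does not match "
                f"({len(self.row_ids)}, {len(self.col_ids)})"
            )

    @property
    def n_rows(self) -> int:
        return len(self.row_ids)

    @property
    def n_features(self) -> int:
        """The feature dimension L."""
        return len(self.col_ids)

    def row_index(self, enzyme_id: str) -> int:
        try:
            return self.row_ids.index(enzyme_id)
        except ValueError:
            raise KeyError(f"unknown enzyme identifier: {enzyme_id!r}") from None

    def row_vector(self, enzyme_id: str) -> np.ndarray:
        return self.cells[self.row_index(enzyme_id)]


@dataclass(frozen=True)
class LabelAssignment:
    """Map from enzyme identifier to its non-empty set of mechanism labels."""

    assignment: Mapping[str, frozenset[str]]

    def __post_init__(self) -> None:
        frozen = {}
        for enzyme_id, labels in dict(self.assignment).items():
            labels = frozenset(labels)
            if not labels:
                raise MatrixFormatError(f"enzyme {enzyme_id!r} has an empty label set")
            if any(not lab for lab in labels):
                raise MatrixFormatError(f"enzyme {enzyme_id!r} has a blank label")
            frozen[enzyme_id] = labels
        object.__setattr__(self, "assignment", frozen)

    def labels_of(self, enzyme_id: str) -> frozenset[str]:
        try:
            return self.assignment[enzyme_id]
        except KeyError:
            raise KeyError(f"no label entry for enzyme {enzyme_id!r}") from None

    @property
    def label_space(self) -> tuple[str, ...]:
        """All labels in use, sorted; its length is J."""
        return tuple(sorted(set().union(*self.assignment.values()))) if self.assignment else ()

    @property
    def n_labels(self) -> int:
        return len(self.label_space)

    def covers(self, matrix: AnnotationMatrix) -> bool:
        return all(rid in self.assignment for rid in matrix.row_ids)

    def require_covers(self, matrix: AnnotationMatrix) -> None:
        missing = [rid for rid in matrix.row_ids if rid not in self.assignment]
        if missing:
            raise MatrixFormatError(f"missing label entries for: {', '.join(missing[:5])}")


@dataclass(frozen=True)
class ClassSizeTable:
    """Ordered (mechanism label, enzyme count) table."""

    entries: tuple[tuple[str, int], ...]

    def __post_init__(self) -> None:
        entries = tuple((str(lab), int(cnt)) for lab, cnt in self.entries)
        labels = [lab for lab, _ in entries]
        if len(set(labels)) != len(labels):
            raise MatrixFormatError("duplicate labels in class-size table")
        for lab, cnt in entries:
            if cnt < 1:
                raise MatrixFormatError(f"count for {lab} must be >= 1, got {cnt}")
        object.__setattr__(self, "entries", entries)

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(lab for lab, _ in self.entries)

    @property
    def total(self) -> int:
        return sum(cnt for _, cnt in self.entries)

    def count_of(self, label: str) -> int:
        for lab, cnt in self.entries:
            if lab == label:
                return cnt
        raise KeyError(f"unknown label {label!r}")

    def __len__(self) -> int:
        return len(self.entries)


@dataclass(frozen=True)
class Prediction:
    """Outcome of classifying one query vector."""

    labels: frozenset[str]
    ring_distance: int
    ring_members: tuple[str, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "labels", frozenset(self.labels))
        object.__setattr__(self, "ring_members", tuple(self.ring_members))
        if not self.labels:
            raise ValueError("prediction must carry at least one label")
        if not self.ring_members:
            raise ValueError("prediction must carry at least one ring member")
        if self.ring_distance < 0:
            raise ValueError("ring distance must be non-negative")


def _format_labels(labels: Iterable[str]) -> str:
    return ";".join(sorted(labels))


def read_matrix(path: str | Path) -> tuple[AnnotationMatrix, LabelAssignment]:
    """Read a paper-layout TSV into an (AnnotationMatrix, LabelAssignment) pair.

    The header row names the signature columns; data rows are
    ``enzyme_id<TAB>0/1 ...<TAB>label[;label...]``.
    """
    path = Path(path)
    with path.open("r", encoding="utf-8", newline="") as handle:
        reader = csv.reader(handle, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            raise MatrixFormatError(f"{path}: empty file") from None
        if len(header) < 3:
            raise MatrixFormatError(
                f"{path}: header must have at least 3 columns (id, >=1 signature, labels)"
            )
        col_ids = tuple(header[1:-1])

        row_ids: list[str] = []
        rows: list[list[int]] = []
        assignment: dict[str, frozenset[str]] = {}
        for lineno, record in enumerate(reader, start=2):
            if not record:
                continue
            if len(record) != len(header):
                raise MatrixFormatError(
                    f"{path}:{lineno}: expected {len(header)} fields, got {len(record)}"
                )
            enzyme_id = record[0]
            if enzyme_id in assignment:
                raise MatrixFormatError(f"{path}:{lineno}: duplicate enzyme identifier {enzyme_id!r}")
            values = []
            for col_id, raw in zip(col_ids, record[1:-1]):
                if raw not in ("0", "1"):
                    raise MatrixFormatError(
                        f"{path}:{lineno}: non-binary cell {raw!r} "
                        f"(enzyme {enzyme_id!r}, signature {col_id!r})"
                    )
                values.append(int(raw))
            label_field = record[-1].strip()
            if not label_field:
                raise MatrixFormatError(
                    f"{path}:{lineno}: empty label field for enzyme {enzyme_id!r}"
                )
            labels = frozenset(part for part in label_field.split(";") if part)
            if not labels:
                raise MatrixFormatError(
                    f"{path}:{lineno}: empty label field for enzyme {enzyme_id!r}"
                )
            row_ids.append(enzyme_id)
            rows.append(values)
            assignment[enzyme_id] = labels

    cells = np.array(rows, dtype=np.uint8).reshape(len(row_ids), len(col_ids))
    matrix = AnnotationMatrix(tuple(row_ids), col_ids, cells)
    return matrix, LabelAssignment(assignment)


def write_matrix(
    matrix: AnnotationMatrix, labels: LabelAssignment, path: str | Path
) -> Path:
    """Write the paper-layout TSV; inverse of :func:`read_matrix`."""
    labels.require_covers(matrix)
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="\n") as handle:
        handle.write("enzyme_id\t" + "\t".join(matrix.col_ids) + "\tlabels\n")
        for i, enzyme_id in enumerate(matrix.row_ids):
            row = "\t".join(str(int(v)) for v in matrix.cells[i])
            handle.write(f"{enzyme_id}\t{row}\t{_format_labels(labels.labels_of(enzyme_id))}\n")
    return path


def parse_class_sizes(text: str) -> ClassSizeTable:
    """Parse ``label<TAB>count`` lines into a :class:`ClassSizeTable`."""
    entries: list[tuple[str, int]] = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        line = line.strip()
        if not line:
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise MatrixFormatError(f"line {lineno}: expected 'label<TAB>count', got {line!r}")
        label, raw_count = parts
        if not _LABEL_RE.match(label):
            raise MatrixFormatError(f"line {lineno}: malformed label {label!r}")
        try:
            count = int(raw_count)
        except ValueError:
            raise MatrixFormatError(f"line {lineno}: malformed count {raw_count!r}") from None
        if count < 1:
            raise MatrixFormatError(f"line {lineno}: count must be >= 1, got {count}")
        entries.append((label, count))
    if not entries:
        raise MatrixFormatError("class-size table is empty")
    return ClassSizeTable(tuple(entries))


def load_class_size_fixture() -> ClassSizeTable:
    """Load the packaged 71-label class-size table."""
    text = resources.files("ringmatch").joinpath("data", CLASS_SIZE_FIXTURE).read_text("utf-8")
    return parse_class_sizes(text)
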