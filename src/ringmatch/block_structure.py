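"""Row/column reordering that exposes block-diagonal structure.

Rows are grouped contiguously by label and every column is assigned to the
label whose enzymes carry it most often; sorting columns by assigned label
concentrates presence cells into label-aligned diagonal blocks.  The
diagonality score is the fraction of presence cells that land inside the
block of their own row's label.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from PIL import Image

from .core_data import AnnotationMatrix, LabelAssignment, load_class_size_fixture

__all__ = ["BlockLayout", "blockify", "reorder", "diagonality_score",
           "render_heatmap", "primary_label"]

PRESENT_RGB = (255, 255, 0)
ABSENT_RGB = (255, 0, 0)


@dataclass(frozen=True)
class BlockLayout:
    """A row permutation, a column permutation, and per-label diagonal blocks.

    ``blocks`` holds (label, (row_start, row_stop), (col_start, col_stop))
    with half-open 0-based spans indexing the REORDERED matrix.  Row spans
    partition all rows; column spans are disjoint, and columns carried by no
    label sit in a trailing unassigned span not listed here.
    """

    row_order: tuple[int, ...]
    col_order: tuple[int, ...]
    blocks: tuple[tuple[str, tuple[int, int], tuple[int, int]], ...]
    score: float


def primary_label(labels: frozenset[str]) -> str:
    """Deterministic primary label of a (possibly multi-label) row: the
    lexicographically smallest label."""
    return min(labels)


def _default_label_order(used: Sequence[str]) -> list[str]:
    """Class-table fixture order when all labels match it, else
    first-appearance order (callers pass first-appearance order in ``used``)."""
    try:
        fixture = load_class_size_fixture().labels
    except Exception:  # fixture missing/corrupt: fall back silently
        return list(used)
    if set(used) <= set(fixture):
        return [lab for lab in fixture if lab in set(used)]
    return list(used)


def blockify(
    matrix: AnnotationMatrix,
    labels: LabelAssignment,
    label_order: Sequence[str] | None = None,
) -> BlockLayout:
    """Deterministic one-pass block-diagonalization.

    Rows are grouped by primary label in ``label_order``; each column is
    assigned to the label whose rows most frequently carry it (ties break to
    the earliest label in ``label_order``), and columns are sorted by
    (assigned label rank, column identifier).  Sorting within a group by
    identifier rather than input position makes the result invariant under
    row/column permutations of the input.
    """
    labels.require_covers(matrix)
    primary = [primary_label(labels.labels_of(rid)) for rid in matrix.row_ids]

    first_appearance: list[str] = []
    seen: set[str] = set()
    for lab in primary:
        if lab not in seen:
            seen.add(lab)
            first_appearance.append(lab)
    if label_order is None:
        order = _default_label_order(first_appearance)
    else:
        order = [lab for lab in label_order if lab in seen]
        order += [lab for lab in first_appearance if lab not in set(order)]
    rank = {lab: k for k, lab in enumerate(order)}

    row_order = sorted(
        range(matrix.n_rows), key=lambda i: (rank[primary[i]], matrix.row_ids[i])
    )

    # per-label presence counts for every column
    counts = np.zeros((len(order), matrix.n_features), dtype=np.int64)
    for i, lab in enumerate(primary):
        counts[rank[lab]] += matrix.cells[i]
    col_label_rank = np.where(counts.any(axis=0), counts.argmax(axis=0), len(order))
    col_order = sorted(
        range(matrix.n_features), key=lambda j: (col_label_rank[j], matrix.col_ids[j])
    )

    blocks = []
    r = 0
    c = 0
    for k, lab in enumerate(order):
        n_rows = sum(1 for p in primary if p == lab)
        n_cols = int(np.count_nonzero(col_label_rank == k))
        blocks.append((lab, (r, r + n_rows), (c, c + n_cols)))
        r += n_rows
        c += n_cols

    layout = BlockLayout(tuple(row_order), tuple(col_order), tuple(blocks), 0.0)
    score = diagonality_score(matrix, layout)
    return BlockLayout(layout.row_order, layout.col_order, layout.blocks, score)


def reorder(matrix: AnnotationMatrix, layout: BlockLayout) -> AnnotationMatrix:
    """Apply the layout's permutations to the matrix."""
    rows = np.asarray(layout.row_order)
    cols = np.asarray(layout.col_order)
    return AnnotationMatrix(
        tuple(matrix.row_ids[i] for i in rows),
        tuple(matrix.col_ids[j] for j in cols),
        matrix.cells[np.ix_(rows, cols)],
    )


def diagonality_score(matrix: AnnotationMatrix, layout: BlockLayout) -> float:
    """Fraction of presence cells inside their own label's diagonal block;
    1.0 for a matrix with no presence cells at all."""
    if sorted(layout.row_order) != list(range(matrix.n_rows)) or sorted(
        layout.col_order
    ) != list(range(matrix.n_features)):
        raise ValueError("layout permutations do not match matrix dimensions")
    reordered = matrix.cells[np.ix_(np.asarray(layout.row_order), np.asarray(layout.col_order))]
    total = int(reordered.sum())
    if total == 0:
        return 1.0
    inside = 0
    for _label, (r0, r1), (c0, c1) in layout.blocks:
        if not (0 <= r0 <= r1 <= matrix.n_rows and 0 <= c0 <= c1 <= matrix.n_features):
            raise ValueError("block spans exceed matrix dimensions")
        inside += int(reordered[r0:r1, c0:c1].sum())
    return inside / total


def render_heatmap(
    matrix: AnnotationMatrix, layout: BlockLayout, path: str | Path
) -> Path:
    """Write a one-pixel-per-cell raster of the reordered matrix.

    Present cells are yellow, absent cells red; image width equals the
    column count.  Format follows the path suffix (.png or .ppm).
    """
    path = Path(path)
    reordered = matrix.cells[np.ix_(np.asarray(layout.row_order), np.asarray(layout.col_order))]
    rgb = np.empty((*reordered.shape, 3), dtype=np.uint8)
    rgb[reordered == 1] = PRESENT_RGB
    rgb[reordered == 0] = ABSENT_RGB
    Image.fromarray(rgb, mode="RGB").save(path)
    return path
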