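"""Nearest-neighbour dictionary search with equal-distance ring voting.

Classification stores all training rows in a dictionary and assigns a
query the label set most common among the ring of nearest neighbours —
all stored rows tied at the minimum squared Euclidean distance, which on
binary vectors equals the Hamming distance and is always a small integer.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np

from .core_data import AnnotationMatrix, LabelAssignment, Prediction

__all__ = [
    "Dictionary",
    "LooRecord",
    "LooReport",
    "squared_distance",
    "nearest_ring",
    "ring_vote",
    "binary_relevance_vote",
    "classify",
    "loo_evaluate",
    "label_set_sort_key",
]

Criterion = Literal["exact", "overlap"]
VoteMode = Literal["set", "per-label"]


@dataclass(frozen=True)
class Dictionary:
    """Training rows plus their label assignment."""

    matrix: AnnotationMatrix
    labels: LabelAssignment

    def __post_init__(self) -> None:
        if self.matrix.n_rows < 1:
            raise ValueError("dictionary must contain at least one row")
        self.labels.require_covers(self.matrix)


@dataclass(frozen=True)
class LooRecord:
    enzyme_id: str
    true_labels: frozenset[str]
    predicted_labels: frozenset[str]
    ring_distance: int
    success: bool


@dataclass(frozen=True)
class LooReport:
    per_enzyme: tuple[LooRecord, ...]
    success_rate: float


def squared_distance(a: Sequence[int] | np.ndarray, b: Sequence[int] | np.ndarray) -> int:
    """Squared Euclidean distance between two binary vectors (= Hamming)."""
    a = np.asarray(a)
    b = np.asarray(b)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError(f"length mismatch: {a.shape} vs {b.shape}")
    return int(np.count_nonzero(a != b))


def nearest_ring(
    query: Sequence[int] | np.ndarray,
    dictionary: Dictionary,
    exclude: str | None = None,
) -> tuple[tuple[str, ...], int]:
    """All dictionary rows at the minimum squared distance from the query.

    Returns (ring member ids in dictionary row order, ring distance).
    """
    query = np.asarray(query)
    matrix = dictionary.matrix
    if query.shape != (matrix.n_features,):
        raise ValueError(
            f"query length {query.shape} does not match feature count {matrix.n_features}"
        )
    keep = np.ones(matrix.n_rows, dtype=bool)
    if exclude is not None:
        keep[matrix.row_index(exclude)] = False
    if not keep.any():
        raise ValueError("dictionary is empty after exclusion")
    distances = np.count_nonzero(matrix.cells != query[np.newaxis, :], axis=1)
    distances = np.where(keep, distances, np.iinfo(np.int64).max)
    best = int(distances.min())
    members = tuple(matrix.row_ids[i] for i in np.flatnonzero(distances == best))
    return members, best


def label_set_sort_key(labels: frozenset[str]) -> tuple[int, tuple[str, ...]]:
    """Deterministic tie-break order on label sets: cardinality, then the
    lexicographic order of the sorted labels."""
    return (len(labels), tuple(sorted(labels)))


def ring_vote(ring_members: Sequence[str], labels: LabelAssignment) -> frozenset[str]:
    """Most common label set in the ring; ties go to the smallest set under
    :func:`label_set_sort_key`."""
    if not ring_members:
        raise ValueError("ring must be non-empty")
    votes = Counter(labels.labels_of(member) for member in ring_members)
    top = max(votes.values())
    return min((s for s, c in votes.items() if c == top), key=label_set_sort_key)


def binary_relevance_vote(
    ring_members: Sequence[str], labels: LabelAssignment
) -> frozenset[str]:
    """Per-label (binary relevance) alternative: keep every label carried by
    a strict majority of the ring; if none reaches a majority, keep the
    label(s) with the most votes."""
    if not ring_members:
        raise ValueError("ring must be non-empty")
    votes: Counter[str] = Counter()
    for member in ring_members:
        votes.update(labels.labels_of(member))
    majority = frozenset(lab for lab, c in votes.items() if 2 * c > len(ring_members))
    if majority:
        return majority
    top = max(votes.values())
    return frozenset(lab for lab, c in votes.items() if c == top)


def classify(
    query: Sequence[int] | np.ndarray,
    dictionary: Dictionary,
    exclude: str | None = None,
    vote: VoteMode = "set",
) -> Prediction:
    """Classify a query vector against the dictionary."""
    members, distance = nearest_ring(query, dictionary, exclude=exclude)
    if vote == "set":
        labels = ring_vote(members, dictionary.labels)
    elif vote == "per-label":
        labels = binary_relevance_vote(members, dictionary.labels)
    else:
        raise ValueError(f"unknown vote mode {vote!r}")
    return Prediction(labels=labels, ring_distance=distance, ring_members=members)


def _is_success(
    predicted: frozenset[str], true: frozenset[str], criterion: Criterion
) -> bool:
    if criterion == "exact":
        return predicted == true
    if criterion == "overlap":
        return bool(predicted & true)
    raise ValueError(f"unknown success criterion {criterion!r}")


def loo_evaluate(
    dictionary: Dictionary,
    criterion: Criterion = "exact",
    vote: VoteMode = "set",
) -> LooReport:
    """Leave-one-out evaluation: each row is classified against the
    dictionary with itself excluded."""
    matrix = dictionary.matrix
    if matrix.n_rows < 2:
        raise ValueError("leave-one-out needs at least 2 rows")
    records = []
    for i, enzyme_id in enumerate(matrix.row_ids):
        prediction = classify(matrix.cells[i], dictionary, exclude=enzyme_id, vote=vote)
        true = dictionary.labels.labels_of(enzyme_id)
        records.append(
            LooRecord(
                enzyme_id=enzyme_id,
                true_labels=true,
                predicted_labels=prediction.labels,
                ring_distance=prediction.ring_distance,
                success=_is_success(prediction.labels, true, criterion),
            )
        )
    rate = sum(rec.success for rec in records) / len(records)
    return LooReport(per_enzyme=tuple(records), success_rate=rate)
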