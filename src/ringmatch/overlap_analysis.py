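"""Per-label feature regions and the overlap structure between them.

A label's region is the union of the signature features carried by its
enzymes; it may decompose into disjoint sub-regions when the enzymes fall
into groups with non-intersecting feature support.  Two labels overlap
completely when their non-empty regions are identical sets (Jaccard 1).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Mapping

import networkx as nx
import numpy as np

from .core_data import AnnotationMatrix, LabelAssignment

__all__ = ["Region", "OverlapReport", "label_region", "sub_subspaces",
           "overlap_report", "jaccard"]


@dataclass(frozen=True)
class Region:
    """Feature region of one label: the union of its enzymes' features and
    its decomposition into disjoint sub-regions (empty when the region is
    itself empty)."""

    label: str
    features: frozenset[str]
    sub_regions: tuple[frozenset[str], ...]


@dataclass(frozen=True)
class OverlapReport:
    pairwise: Mapping[frozenset[str], float]
    complete_pairs: tuple[tuple[str, str], ...]
    shared_features: Mapping[tuple[str, str], frozenset[str]]
    empty_labels: tuple[str, ...] = ()


def jaccard(a: frozenset[str], b: frozenset[str]) -> float:
    """|A ∩ B| / |A ∪ B|; 0.0 when both sets are empty."""
    union = a | b
    if not union:
        return 0.0
    return len(a & b) / len(union)


def _member_rows(
    matrix: AnnotationMatrix, labels: LabelAssignment, label: str
) -> list[int]:
    rows = [
        i for i, rid in enumerate(matrix.row_ids) if label in labels.labels_of(rid)
    ]
    if not rows:
        raise KeyError(f"label {label!r} has no enzymes")
    return rows


def sub_subspaces(
    matrix: AnnotationMatrix, labels: LabelAssignment, label: str
) -> list[frozenset[str]]:
    """Disjoint sub-regions of one label's feature region.

    Enzymes of the label form a graph with an edge whenever two feature
    sets intersect; each connected component contributes the union of its
    members' features.  Components whose union is empty (enzymes with no
    signatures) are dropped.
    """
    rows = _member_rows(matrix, labels, label)
    feats = {
        i: frozenset(
            matrix.col_ids[j] for j in np.flatnonzero(matrix.cells[i])
        )
        for i in rows
    }
    graph = nx.Graph()
    graph.add_nodes_from(rows)
    for i, j in combinations(rows, 2):
        if feats[i] & feats[j]:
            graph.add_edge(i, j)
    components = sorted(nx.connected_components(graph), key=min)
    unions = [frozenset().union(*(feats[i] for i in comp)) for comp in components]
    return [u for u in unions if u]


def label_region(
    matrix: AnnotationMatrix, labels: LabelAssignment, label: str
) -> Region:
    """The label's feature region (union over its enzymes) with sub-regions."""
    rows = _member_rows(matrix, labels, label)
    mask = matrix.cells[rows].any(axis=0)
    features = frozenset(matrix.col_ids[j] for j in np.flatnonzero(mask))
    subs = tuple(sub_subspaces(matrix, labels, label))
    return Region(label=label, features=features, sub_regions=subs)


def overlap_report(
    matrix: AnnotationMatrix, labels: LabelAssignment, min_jaccard: float = 0.0
) -> OverlapReport:
    """Jaccard overlap for every unordered label pair, plus the complete
    (identical, non-empty) pairs and their shared feature sets.

    ``min_jaccard`` filters the pairwise map only; complete-pair detection
    always sees every pair.
    """
    space = labels.label_space
    if len(space) < 2:
        raise ValueError("overlap analysis needs at least 2 labels")
    regions = {lab: label_region(matrix, labels, lab) for lab in space}
    empty = tuple(lab for lab in space if not regions[lab].features)

    pairwise: dict[frozenset[str], float] = {}
    complete: list[tuple[str, str]] = []
    shared: dict[tuple[str, str], frozenset[str]] = {}
    for a, b in combinations(space, 2):
        fa, fb = regions[a].features, regions[b].features
        score = jaccard(fa, fb)
        if score >= min_jaccard:
            pairwise[frozenset((a, b))] = score
        if fa and fa == fb:
            complete.append((a, b))
            shared[(a, b)] = fa
    return OverlapReport(
        pairwise=pairwise,
        complete_pairs=tuple(complete),
        shared_features=shared,
        empty_labels=empty,
    )
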