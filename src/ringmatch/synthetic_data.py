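"""Synthetic annotation matrices with planted block structure.

Generates single-label enzymes whose signature rows are exact copies of a
per-label column block: blocks are pairwise disjoint except for one
designated label pair that shares a single block (a planted complete
overlap), and one designated composite label whose block is split into
disjoint sub-blocks with its enzymes divided among them.  Optional
symmetric bit-flip noise perturbs the matrix afterwards.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .core_data import (
    AnnotationMatrix,
    ClassSizeTable,
    LabelAssignment,
    load_class_size_fixture,
)

__all__ = [
    "OverlapSpec",
    "CompositeSpec",
    "GeneratorConfig",
    "PlantedStructure",
    "default_config",
    "allocate_blocks",
    "generate",
    "add_noise",
    "shuffle_columns",
    "enzyme_ids",
]

DEFAULT_N_FEATURES = 321
DEFAULT_OVERLAP = ("M0348", "M0269", 4)
DEFAULT_COMPOSITE = ("M0218", 2)


@dataclass(frozen=True)
class OverlapSpec:
    """Two labels planted with one identical shared column block."""

    label_a: str
    label_b: str
    shared_width: int = 4


@dataclass(frozen=True)
class CompositeSpec:
    """A label whose block is a union of disjoint sub-blocks."""

    label: str
    n_subblocks: int = 2


@dataclass(frozen=True)
class GeneratorConfig:
    class_sizes: ClassSizeTable
    n_features: int = DEFAULT_N_FEATURES
    overlap_pair: OverlapSpec | None = None
    composite_label: CompositeSpec | None = None
    noise_rate: float = 0.0
    seed: int = 0


def default_config(seed: int = 0, noise_rate: float = 0.0) -> GeneratorConfig:
    """The default configuration: packaged class sizes, 321 features, one
    complete-overlap pair sharing a 4-column block, one composite label with
    two sub-blocks."""
    return GeneratorConfig(
        class_sizes=load_class_size_fixture(),
        n_features=DEFAULT_N_FEATURES,
        overlap_pair=OverlapSpec(*DEFAULT_OVERLAP),
        composite_label=CompositeSpec(*DEFAULT_COMPOSITE),
        noise_rate=noise_rate,
        seed=seed,
    )


@dataclass(frozen=True)
class PlantedStructure:
    """Ground truth of a generated matrix.

    ``block_of_label`` maps every label to its ordered block columns (the
    overlap pair maps to one identical tuple).  ``subblock_assignment`` maps
    each composite-label enzyme to the index of the sub-block it occupies;
    ``composite_sub_blocks`` lists the sub-blocks' column tuples.
    """

    block_of_label: Mapping[str, tuple[str, ...]]
    subblock_assignment: Mapping[str, int] = field(default_factory=dict)
    composite_sub_blocks: tuple[tuple[str, ...], ...] = ()

    def columns_of(self, label: str) -> frozenset[str]:
        return frozenset(self.block_of_label[label])


def _validate(config: GeneratorConfig) -> None:
    labels = set(config.class_sizes.labels)
    if not 0.0 <= config.noise_rate <= 1.0:
        raise ValueError(f"noise_rate must lie in [0, 1], got {config.noise_rate}")
    ov, comp = config.overlap_pair, config.composite_label
    if ov is not None:
        if ov.label_a == ov.label_b:
            raise ValueError("overlap pair labels must differ")
        for lab in (ov.label_a, ov.label_b):
            if lab not in labels:
                raise ValueError(f"overlap label {lab!r} not in class-size table")
        if ov.shared_width < 1:
            raise ValueError("shared_width must be >= 1")
    if comp is not None:
        if comp.label not in labels:
            raise ValueError(f"composite label {comp.label!r} not in class-size table")
        if comp.n_subblocks < 2:
            raise ValueError("composite label needs at least 2 sub-blocks")
        if ov is not None and comp.label in (ov.label_a, ov.label_b):
            raise ValueError("composite label must be distinct from the overlap pair")
        if config.class_sizes.count_of(comp.label) < comp.n_subblocks:
            raise ValueError("composite label has fewer enzymes than sub-blocks")


def enzyme_ids(class_sizes: ClassSizeTable) -> dict[str, tuple[str, ...]]:
    """Deterministic accession-like identifiers, one per class-count unit."""
    out: dict[str, tuple[str, ...]] = {}
    serial = 0
    for label, count in class_sizes.entries:
        out[label] = tuple(f"E{serial + k:04d}" for k in range(count))
        serial += count
    return out


def allocate_blocks(config: GeneratorConfig) -> PlantedStructure:
    """Partition the feature budget into per-label column blocks.

    Every block starts at width 1 (the shared overlap block is pinned at
    ``shared_width``) and the remaining budget is distributed round-robin in
    class-table order, so widths sum to exactly ``n_features``.
    """
    _validate(config)
    ov, comp = config.overlap_pair, config.composite_label
    labels = list(config.class_sizes.labels)

    # one block per label, except the overlap partner reuses label_a's block
    block_owner = [lab for lab in labels if ov is None or lab != ov.label_b]
    widths = {lab: 1 for lab in block_owner}
    fixed = set()
    if ov is not None:
        widths[ov.label_a] = ov.shared_width
        fixed.add(ov.label_a)
    base = sum(widths.values())
    if config.n_features < base:
        raise ValueError(
            f"n_features={config.n_features} is below the required minimum {base} "
            f"({len(block_owner)} blocks)"
        )
    growable = [lab for lab in block_owner if lab not in fixed]
    budget = config.n_features - base
    if budget and not growable:
        raise ValueError("feature budget exceeds the total width of fixed blocks")
    i = 0
    while budget > 0:
        widths[growable[i % len(growable)]] += 1
        budget -= 1
        i += 1

    if comp is not None and widths[comp.label] < comp.n_subblocks:
        raise ValueError(
            f"composite block width {widths[comp.label]} is below the "
            f"{comp.n_subblocks} sub-blocks requested; increase n_features"
        )

    block_of_label: dict[str, tuple[str, ...]] = {}
    next_col = 0
    for lab in block_owner:
        cols = tuple(f"S{next_col + k:04d}" for k in range(widths[lab]))
        next_col += widths[lab]
        block_of_label[lab] = cols
    if ov is not None:
        block_of_label[ov.label_b] = block_of_label[ov.label_a]

    subblock_assignment: dict[str, int] = {}
    sub_blocks: tuple[tuple[str, ...], ...] = ()
    if comp is not None:
        cols = block_of_label[comp.label]
        n = comp.n_subblocks
        # contiguous split, widths as even as possible
        bounds = [round(k * len(cols) / n) for k in range(n + 1)]
        sub_blocks = tuple(tuple(cols[bounds[k]:bounds[k + 1]]) for k in range(n))
        ids = enzyme_ids(config.class_sizes)[comp.label]
        count = len(ids)
        for k, enzyme in enumerate(ids):
            subblock_assignment[enzyme] = k * n // count

    return PlantedStructure(block_of_label, subblock_assignment, sub_blocks)


def generate(
    config: GeneratorConfig,
) -> tuple[AnnotationMatrix, LabelAssignment, PlantedStructure]:
    """Generate a matrix realising the planted structure.

    Each enzyme carries exactly one label; its row is 1 on its label's block
    columns (composite enzymes: on their sub-block's columns) and 0
    elsewhere, before noise.  Deterministic given the config seed.
    """
    structure = allocate_blocks(config)
    ids = enzyme_ids(config.class_sizes)
    # column order: grouped by block, in class-table order of the owning label
    col_ids: list[str] = []
    seen: set[str] = set()
    for label in config.class_sizes.labels:
        for col in structure.block_of_label[label]:
            if col not in seen:
                seen.add(col)
                col_ids.append(col)
    col_index = {col: i for i, col in enumerate(col_ids)}

    comp = config.composite_label
    row_ids: list[str] = []
    assignment: dict[str, frozenset[str]] = {}
    cells = np.zeros((config.class_sizes.total, len(col_ids)), dtype=np.uint8)
    r = 0
    for label, _count in config.class_sizes.entries:
        for enzyme in ids[label]:
            if comp is not None and label == comp.label:
                cols = structure.composite_sub_blocks[structure.subblock_assignment[enzyme]]
            else:
                cols = structure.block_of_label[label]
            cells[r, [col_index[c] for c in cols]] = 1
            row_ids.append(enzyme)
            assignment[enzyme] = frozenset({label})
            r += 1

    matrix = AnnotationMatrix(tuple(row_ids), tuple(col_ids), cells)
    if config.noise_rate > 0:
        matrix = add_noise(matrix, config.noise_rate, config.seed)
    return matrix, LabelAssignment(assignment), structure


def add_noise(matrix: AnnotationMatrix, noise_rate: float, seed: int) -> AnnotationMatrix:
    """Flip each cell independently with probability ``noise_rate``."""
    if not 0.0 <= noise_rate <= 1.0:
        raise ValueError(f"noise_rate must lie in [0, 1], got {noise_rate}")
    rng = np.random.default_rng(seed)
    flips = rng.random(matrix.cells.shape) < noise_rate
    cells = np.where(flips, 1 - matrix.cells, matrix.cells).astype(np.uint8)
    return AnnotationMatrix(matrix.row_ids, matrix.col_ids, cells)


def shuffle_columns(matrix: AnnotationMatrix, seed: int) -> AnnotationMatrix:
    """Permute the columns uniformly at random (ids travel with their cells)."""
    rng = np.random.default_rng(seed)
    perm = rng.permutation(matrix.n_features)
    return AnnotationMatrix(
        matrix.row_ids,
        tuple(matrix.col_ids[i] for i in perm),
        matrix.cells[:, perm],
    )
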