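# ringmatch

Ring-voting nearest-neighbour classification and block-structure analysis of
binary enzyme × signature annotation matrices.

An annotation matrix records presence/absence of signature features (e.g.
protein family/domain identifiers) for a set of enzymes, each carrying one or
more mechanism labels. `ringmatch` provides:

- **core_data** — domain types, the paper-layout TSV format
  (`enzyme_id <TAB> 0/1 ... <TAB> label[;label]`), and a packaged 71-label
  class-size table.
- **synthetic_data** — a generator of matrices with planted per-label column
  blocks: near-disjoint blocks, one completely overlapping label pair sharing
  a 4-column block, one composite label split across disjoint sub-blocks, and
  optional symmetric bit-flip noise.
- **ring_knn** — k=1 nearest-neighbour "dictionary search" under squared
  Euclidean (= Hamming) distance with equal-distance *ring voting*, plus
  leave-one-out evaluation.
- **block_structure** — deterministic row/column reordering that exposes
  block-diagonal structure, a diagonality score, and a yellow/red heatmap
  renderer.
- **overlap_analysis** — per-label feature regions, decomposition into
  disjoint sub-regions, and pairwise Jaccard overlap with complete-overlap
  detection.
- **template_cli** — template look-up prediction (distinct row patterns as
  templates with a distance threshold and abstention) and the command-line
  interface.

## CLI

All functionality is exposed through the `ringmatch` command:

```sh
# generate the default synthetic dataset (247 enzymes x 321 features)
ringmatch simulate --out matrix.tsv --structure planted.tsv --seed 0

# leave-one-out ring-voting evaluation
ringmatch loo matrix.tsv --criterion exact --vote set --out loo.tsv

# block-diagonalize and render a heatmap
ringmatch blockify matrix.tsv --out reordered.tsv --layout layout.tsv --heatmap map.png

# pairwise region overlap
ringmatch overlap matrix.tsv --out overlap.tsv

# match novel enzymes against the template library
ringmatch predict --templates matrix.tsv --query queries.tsv --threshold 0 --out pred.tsv
```

`simulate` accepts a YAML config (`--config`) with keys `n_features`,
`noise_rate`, `seed`, `shuffle`, `class_sizes` (path to a `label<TAB>count`
TSV), `overlap` (`{label_a, label_b, shared_width}` or `null`) and
`composite` (`{label, n_subblocks}` or `null`).

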