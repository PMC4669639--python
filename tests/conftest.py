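import numpy as np
import pytest

from ringmatch.core_data import AnnotationMatrix, ClassSizeTable, LabelAssignment
from ringmatch import synthetic_data as sd


@pytest.fixture(scope="session")
def default_dataset():
    """Default noiseless synthetic dataset (packaged class sizes, 321
    features, planted overlap pair and composite label, seed 0)."""
    return sd.generate(sd.default_config(seed=0))


@pytest.fixture(scope="session")
def no_overlap_dataset():
    """Same as the default but without the planted complete-overlap pair."""
    config = sd.GeneratorConfig(
        class_sizes=sd.load_class_size_fixture(),
        n_features=321,
        overlap_pair=None,
        composite_label=sd.CompositeSpec("M0218", 2),
        seed=0,
    )
    return sd.generate(config)


def make_matrix(rows, col_ids, row_ids=None):
    """Build an AnnotationMatrix from a list of 0/1 row lists."""
    rows = np.asarray(rows, dtype=np.uint8)
    if row_ids is None:
        row_ids = tuple(f"E{i}" for i in range(rows.shape[0]))
    return AnnotationMatrix(tuple(row_ids), tuple(col_ids), rows)


def make_labels(mapping):
    return LabelAssignment({k: frozenset(v) for k, v in mapping.items()})


def random_matrix(rng, n_rows, n_cols, density=0.3):
    cells = (rng.random((n_rows, n_cols)) < density).astype(np.uint8)
    row_ids = tuple(f"E{i:03d}" for i in range(n_rows))
    col_ids = tuple(f"S{j:03d}" for j in range(n_cols))
    return AnnotationMatrix(row_ids, col_ids, cells)


@pytest.fixture
def toy_two_label():
    """2 labels x 2 identical enzymes each, disjoint 2-column blocks."""
    table = ClassSizeTable((("M0001", 2), ("M0002", 2)))
    config = sd.GeneratorConfig(class_sizes=table, n_features=4)
    return sd.generate(config)
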