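import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ringmatch.core_data import ClassSizeTable
from ringmatch import ring_knn as rk
from ringmatch import synthetic_data as sd

from conftest import make_labels, make_matrix, random_matrix

binary_vectors = st.integers(1, 30).flatmap(
    lambda n: st.tuples(
        *[st.lists(st.integers(0, 1), min_size=n, max_size=n) for _ in range(3)]
    )
)


def brute_force_distance(a, b):
    return sum(1 for x, y in zip(a, b) if x != y)


def brute_force_ring(query, matrix, row_ids, exclude=None):
    best = None
    members = []
    for rid, row in zip(row_ids, matrix):
        if rid == exclude:
            continue
        d = brute_force_distance(query, row)
        if best is None or d < best:
            best, members = d, [rid]
        elif d == best:
            members.append(rid)
    return members, best


class TestSquaredDistance:
    def test_identity(self):
        x = np.array([0, 1, 1, 0])
        assert rk.squared_distance(x, x) == 0

    def test_complement(self):
        assert rk.squared_distance([0, 0, 0, 0], [1, 1, 1, 1]) == 4

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            rk.squared_distance([0, 1], [0, 1, 0])

    def test_matches_brute_force_on_random_pairs(self):
        rng = np.random.default_rng(11)
        for _ in range(200):
            a = rng.integers(0, 2, 321)
            b = rng.integers(0, 2, 321)
            assert rk.squared_distance(a, b) == brute_force_distance(a, b)

    @settings(max_examples=100, deadline=None)
    @given(binary_vectors)
    def test_metric_axioms(self, vectors):
        a, b, c = (np.array(v) for v in vectors)
        dab = rk.squared_distance(a, b)
        assert dab >= 0
        assert (dab == 0) == bool(np.array_equal(a, b))
        assert dab == rk.squared_distance(b, a)
        assert dab <= rk.squared_distance(a, c) + rk.squared_distance(c, b)


@pytest.fixture
def small_dictionary():
    matrix = make_matrix(
        [[1, 0, 0], [0, 1, 0], [0, 0, 1], [1, 1, 1]],
        ["s1", "s2", "s3"],
        row_ids=["e1", "e2", "e3", "e4"],
    )
    labels = make_labels(
        {"e1": {"A"}, "e2": {"B"}, "e3": {"B"}, "e4": {"A", "B"}}
    )
    return rk.Dictionary(matrix, labels)


class TestNearestRing:
    def test_exact_hit(self, small_dictionary):
        members, dist = rk.nearest_ring([1, 0, 0], small_dictionary)
        assert members == ("e1",) and dist == 0

    def test_equidistant_ring_of_three(self, small_dictionary):
        # all-zero query: distance 1 to e1,e2,e3 and 3 to e4
        members, dist = rk.nearest_ring([0, 0, 0], small_dictionary)
        assert members == ("e1", "e2", "e3") and dist == 1

    def test_exclusion(self, small_dictionary):
        members, dist = rk.nearest_ring([1, 0, 0], small_dictionary, exclude="e1")
        assert dist == 2
        assert members == ("e2", "e3", "e4")

    def test_empty_after_exclusion(self):
        matrix = make_matrix([[1]], ["s1"], row_ids=["e1"])
        d = rk.Dictionary(matrix, make_labels({"e1": {"A"}}))
        with pytest.raises(ValueError):
            rk.nearest_ring([1], d, exclude="e1")

    def test_matches_brute_force_scan(self):
        rng = np.random.default_rng(23)
        matrix = random_matrix(rng, 30, 15)
        labels = make_labels({rid: {"A"} for rid in matrix.row_ids})
        dictionary = rk.Dictionary(matrix, labels)
        for _ in range(50):
            query = rng.integers(0, 2, 15)
            got = rk.nearest_ring(query, dictionary)
            expected = brute_force_ring(query, matrix.cells, matrix.row_ids)
            assert got == (tuple(expected[0]), expected[1])

    def test_invariant_under_row_permutation(self):
        rng = np.random.default_rng(5)
        matrix = random_matrix(rng, 12, 8)
        labels = make_labels({rid: {"A"} for rid in matrix.row_ids})
        perm = rng.permutation(12)
        permuted = make_matrix(
            matrix.cells[perm], matrix.col_ids,
            row_ids=[matrix.row_ids[i] for i in perm],
        )
        for _ in range(20):
            query = rng.integers(0, 2, 8)
            m1, d1 = rk.nearest_ring(query, rk.Dictionary(matrix, labels))
            m2, d2 = rk.nearest_ring(query, rk.Dictionary(permuted, labels))
            assert d1 == d2 and set(m1) == set(m2)


class TestRingVote:
    def test_strict_majority(self):
        labels = make_labels({"e1": {"A"}, "e2": {"B"}, "e3": {"B"}})
        assert rk.ring_vote(["e1", "e2", "e3"], labels) == frozenset({"B"})

    def test_single_member_multilabel(self):
        labels = make_labels({"e1": {"A", "B"}})
        assert rk.ring_vote(["e1"], labels) == frozenset({"A", "B"})

    def test_tie_break_documented_rule(self):
        # tie between {A} and {B}: equal cardinality, lexicographic -> {A}
        labels = make_labels({"e1": {"A"}, "e2": {"A"}, "e3": {"B"}, "e4": {"B"}})
        assert rk.ring_vote(["e1", "e2", "e3", "e4"], labels) == frozenset({"A"})

    def test_tie_break_prefers_smaller_set(self):
        labels = make_labels({"e1": {"A", "B"}, "e2": {"C"}})
        assert rk.ring_vote(["e1", "e2"], labels) == frozenset({"C"})

    def test_empty_ring_rejected(self):
        with pytest.raises(ValueError):
            rk.ring_vote([], make_labels({"e1": {"A"}}))

    def test_unlabelled_member_rejected(self):
        with pytest.raises(KeyError):
            rk.ring_vote(["ghost"], make_labels({"e1": {"A"}}))


class TestBinaryRelevanceVote:
    def test_majority_labels_kept(self):
        labels = make_labels({"e1": {"A", "B"}, "e2": {"A"}, "e3": {"A", "C"}})
        assert rk.binary_relevance_vote(["e1", "e2", "e3"], labels) == frozenset({"A"})

    def test_fallback_to_plurality(self):
        labels = make_labels({"e1": {"A"}, "e2": {"B"}, "e3": {"C"}, "e4": {"A"}})
        # A has 2/4 votes: not a strict majority, but the unique plurality
        assert rk.binary_relevance_vote(["e1", "e2", "e3", "e4"], labels) == frozenset({"A"})


class TestClassify:
    def test_unique_block_label_at_distance_zero(self, toy_two_label):
        matrix, labels, _ = toy_two_label
        d = rk.Dictionary(matrix, labels)
        pred = rk.classify(matrix.cells[0], d)
        assert pred.labels == labels.labels_of(matrix.row_ids[0])
        assert pred.ring_distance == 0

    def test_overlap_pair_gives_four_member_ring(self, default_dataset):
        matrix, labels, _ = default_dataset
        d = rk.Dictionary(matrix, labels)
        row = next(
            i for i, rid in enumerate(matrix.row_ids)
            if labels.labels_of(rid) == frozenset({"M0348"})
        )
        pred = rk.classify(matrix.cells[row], d)
        assert pred.ring_distance == 0
        assert len(pred.ring_members) == 4

    def test_single_row_dictionary(self):
        matrix = make_matrix([[1, 0]], ["s1", "s2"], row_ids=["e1"])
        d = rk.Dictionary(matrix, make_labels({"e1": {"A", "B"}}))
        pred = rk.classify([0, 1], d)
        assert pred.labels == frozenset({"A", "B"})
        assert pred.ring_distance == 2


class TestLooEvaluate:
    def test_two_disjoint_labels_perfect(self, toy_two_label):
        matrix, labels, _ = toy_two_label
        report = rk.loo_evaluate(rk.Dictionary(matrix, labels))
        assert report.success_rate == 1.0

    def test_singleton_class_fails(self):
        table = ClassSizeTable((("M0001", 2), ("M0002", 1)))
        matrix, labels, _ = sd.generate(
            sd.GeneratorConfig(class_sizes=table, n_features=4)
        )
        report = rk.loo_evaluate(rk.Dictionary(matrix, labels))
        n = matrix.n_rows
        assert report.success_rate == pytest.approx((n - 1) / n)
        failed = [r for r in report.per_enzyme if not r.success]
        assert len(failed) == 1
        assert failed[0].true_labels == frozenset({"M0002"})

    def test_default_dataset_errors_only_in_overlap_pair(self, default_dataset):
        matrix, labels, _ = default_dataset
        report = rk.loo_evaluate(rk.Dictionary(matrix, labels))
        for rec in report.per_enzyme:
            if not rec.success:
                assert rec.true_labels & {"M0348", "M0269"}

    def test_success_rate_definition(self, default_dataset):
        matrix, labels, _ = default_dataset
        report = rk.loo_evaluate(rk.Dictionary(matrix, labels))
        n_success = sum(r.success for r in report.per_enzyme)
        assert report.success_rate == n_success / len(report.per_enzyme)

    def test_requires_two_rows(self):
        matrix = make_matrix([[1]], ["s1"], row_ids=["e1"])
        d = rk.Dictionary(matrix, make_labels({"e1": {"A"}}))
        with pytest.raises(ValueError):
            rk.loo_evaluate(d)

    def test_overlap_criterion_at_least_exact(self, default_dataset):
        matrix, labels, _ = default_dataset
        d = rk.Dictionary(matrix, labels)
        exact = rk.loo_evaluate(d, criterion="exact")
        loose = rk.loo_evaluate(d, criterion="overlap")
        assert loose.success_rate >= exact.success_rate


class TestNoiseMonotonicity:
    def test_mean_success_non_increasing_in_noise(self):
        # small dataset for speed; the full-scale check is in the acceptance suite
        table = ClassSizeTable(tuple(sd.load_class_size_fixture().entries[:15]))
        rates = [0.0, 0.1, 0.3]
        means = []
        for rate in rates:
            scores = []
            for seed in range(8):
                config = sd.GeneratorConfig(
                    class_sizes=table, n_features=60, noise_rate=rate, seed=seed
                )
                matrix, labels, _ = sd.generate(config)
                scores.append(
                    rk.loo_evaluate(rk.Dictionary(matrix, labels)).success_rate
                )
            means.append(np.mean(scores))
        for lo, hi in zip(means[1:], means[:-1]):
            assert lo <= hi + 0.05
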