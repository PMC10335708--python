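import numpy as np
import pytest

from mtann.evaluation import (
    annotation_accuracy,
    ar_index,
    auprc,
    f1_unassigned,
    make_benchmark_tests,
    threshold_from_true_proportion,
)
from mtann.simulate import SimulationConfig, simulate_collection


def brute_force_auprc(scores, positives):
    """Step-integration PR oracle: AP = sum over positives-sorted
    thresholds of (recall step) * precision."""
    order = np.argsort(-np.asarray(scores, dtype=float), kind="stable")
    pos = np.asarray(positives, dtype=bool)[order]
    n_pos = pos.sum()
    tp = fp = 0
    ap = 0.0
    last_recall = 0.0
    scores_sorted = np.asarray(scores, dtype=float)[order]
    i = 0
    n = len(pos)
    while i < n:
        j = i
        while j < n and scores_sorted[j] == scores_sorted[i]:
            j += 1
        tp += int(pos[i:j].sum())
        fp += (j - i) - int(pos[i:j].sum())
        recall = tp / n_pos
        precision = tp / (tp + fp)
        ap += (recall - last_recall) * precision
        last_recall = recall
        i = j
    return ap


class TestAuprc:
    def test_perfect_separation(self):
        scores = np.array([0.9, 0.8, 0.1, 0.2])
        mask = np.array([True, True, False, False])
        assert auprc(scores, mask) == pytest.approx(1.0)

    def test_constant_scores_equal_prevalence(self):
        scores = np.full(20, 0.5)
        mask = np.array([True] * 5 + [False] * 15)
        assert auprc(scores, mask) == pytest.approx(0.25)

    def test_matches_brute_force(self, rng):
        for _ in range(5):
            scores = rng.random(40)
            mask = rng.random(40) < 0.3
            if not mask.any() or mask.all():
                continue
            assert auprc(scores, mask) == pytest.approx(
                brute_force_auprc(scores, mask), abs=1e-12
            )

    def test_degenerate_mask_rejected(self):
        with pytest.raises(ValueError):
            auprc(np.array([0.1, 0.2]), np.array([True, True]))


class TestF1:
    def test_perfect_flagging(self):
        labels = ["unassigned", "unassigned", "A"]
        mask = [True, True, False]
        assert f1_unassigned(labels, mask) == 1.0

    def test_nothing_flagged_with_positives_present(self):
        assert f1_unassigned(["A", "B"], [True, False]) == 0.0

    def test_nothing_flagged_nothing_true(self):
        assert f1_unassigned(["A", "B"], [False, False]) == 1.0

    def test_half_correct_hand_computed(self):
        # tp=1, fp=1, fn=1: precision=recall=0.5 -> F1=0.5
        labels = ["unassigned", "unassigned", "A", "B"]
        mask = [True, False, True, False]
        assert f1_unassigned(labels, mask) == pytest.approx(0.5)


class TestAccuracy:
    def test_all_correct_with_unseen_flagged(self):
        pred = ["A", "B", "unassigned"]
        true = ["A", "B", "novel"]
        mask = [False, False, True]
        assert annotation_accuracy(pred, true, mask) == 1.0

    def test_unseen_labeled_as_shared_counts_wrong(self):
        pred = ["A", "A"]
        true = ["A", "novel"]
        mask = [False, True]
        assert annotation_accuracy(pred, true, mask) == 0.5

    def test_ten_cell_hand_count(self):
        pred = ["A", "A", "B", "B", "unassigned", "C", "A", "unassigned", "B", "C"]
        true = ["A", "B", "B", "B", "x", "C", "A", "y", "A", "B"]
        mask = [False, False, False, False, True, False, False, True, False, False]
        # correct: 0,2,3,4,5,6,7 -> 7/10
        assert annotation_accuracy(pred, true, mask) == pytest.approx(0.7)

    def test_invariant_to_permutation(self, rng):
        pred = np.array(["A", "B", "unassigned", "A"], dtype=object)
        true = np.array(["A", "B", "x", "B"], dtype=object)
        mask = np.array([False, False, True, False])
        perm = rng.permutation(4)
        assert annotation_accuracy(pred, true, mask) == annotation_accuracy(
            pred[perm], true[perm], mask[perm]
        )


class TestArIndex:
    def test_wins_over_losses(self):
        a = [1, 1, 1, 1, 1, 1, 0, 0, 0]
        b = [0, 0, 0, 0, 0, 0, 1, 1, 1]
        assert ar_index(a, b) == pytest.approx(2.0)

    def test_equal_wins(self):
        assert ar_index([1, 0], [0, 1]) == pytest.approx(1.0)

    def test_all_ties_undefined(self):
        assert ar_index([1.0, 2.0], [1.0, 2.0]) is None

    def test_no_losses_is_infinite(self):
        assert ar_index([2, 2], [1, 1]) == float("inf")


class TestTrueProportionThreshold:
    def test_top_fraction_flagged(self):
        m = np.arange(10) / 10.0
        mask = threshold_from_true_proportion(m, 0.2)
        assert mask.sum() == 2
        assert mask[-2:].all()

    def test_small_p_flags_little(self):
        m = np.linspace(0, 1, 100)
        assert threshold_from_true_proportion(m, 0.01).sum() == 1

    def test_ties_at_boundary_all_flagged(self):
        m = np.array([0.1, 0.5, 0.5, 0.5, 0.9])
        mask = threshold_from_true_proportion(m, 0.4)  # k = 2
        assert mask.sum() == 4  # the three tied 0.5s join the 0.9

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            threshold_from_true_proportion(np.array([0.1]), 1.5)


@pytest.fixture(scope="module")
def collection():
    cfg = SimulationConfig(
        n_refs=2, n_types=4, cells_per_type=12, n_genes=60,
        n_markers_per_type=3, seed=13,
    )
    refs, query, _ = simulate_collection(cfg)
    return refs, query


class TestBenchmarkHarness:

    def test_one_test_per_shared_type(self, collection):
        refs, query = collection
        tests = make_benchmark_tests(refs, query)
        assert len(tests) == 4
        assert sorted(t.held_out_type for t in tests) == [
            "type0", "type1", "type2", "type3"
        ]

    def test_held_out_type_absent_from_references(self, collection):
        refs, query = collection
        for test in make_benchmark_tests(refs, query):
            for ref in test.references:
                assert test.held_out_type not in set(ref.labels)

    def test_query_untouched_and_mask_consistent(self, collection):
        refs, query = collection
        for test in make_benchmark_tests(refs, query):
            assert test.query is query
            np.testing.assert_array_equal(
                test.unseen_mask, np.asarray(query.labels) == test.held_out_type
            )
            assert test.p == pytest.approx(test.unseen_mask.mean())
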