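"""Tests for the subsampling protocol, Kuncheva stability and NCC metrics."""

import numpy as np
import pandas as pd
import pytest

from reglrsd import (
    AbundanceTable,
    CentroidModel,
    ProtocolConfig,
    ProtocolError,
    average_consistency,
    classification_metrics,
    fit_ncc,
    kuncheva_index,
    pairwise_kuncheva,
    predict_ncc,
    run_protocol,
    subsample_split,
)
from reglrsd.scoring import rank_markers

from conftest import make_labeled_table


class TestSubsampleSplit:
    @pytest.mark.parametrize("n, n_pos, expected_train", [(22, 10, 18), (10, 5, 8)])
    def test_ceil_rule_sizes(self, n, n_pos, expected_train):
        table = make_labeled_table(p=4, n=n, n_pos=n_pos, seed=1)
        train, test = subsample_split(table, 0.8, rng_seed=0)
        assert train.n == expected_train
        assert test.n == n - expected_train

    def test_same_seed_identical_split(self, labeled_table):
        a = subsample_split(labeled_table, 0.8, rng_seed=7)
        b = subsample_split(labeled_table, 0.8, rng_seed=7)
        assert a[0].sample_ids == b[0].sample_ids
        assert a[1].sample_ids == b[1].sample_ids

    def test_partition_is_disjoint_and_complete(self, labeled_table):
        train, test = subsample_split(labeled_table, 0.8, rng_seed=3)
        got = sorted(train.sample_ids + test.sample_ids)
        assert got == sorted(labeled_table.sample_ids)
        assert not set(train.sample_ids) & set(test.sample_ids)

    def test_stratified_keeps_both_classes(self):
        table = make_labeled_table(p=3, n=20, n_pos=6, seed=2)
        for seed in range(10):
            train, test = subsample_split(table, 0.8, rng_seed=seed)
            for part in (train, test):
                assert len(set(part.labels[s] for s in part.sample_ids)) == 2

    def test_emptied_class_raises(self):
        # ceil(0.8 * 2) = 2 leaves no test sample for the small class
        table = make_labeled_table(p=3, n=10, n_pos=2, seed=0)
        with pytest.raises(ProtocolError, match="healthy"):
            subsample_split(table, 0.8, rng_seed=0)

    def test_invalid_fraction(self, labeled_table):
        with pytest.raises(ValueError):
            subsample_split(labeled_table, 1.0, rng_seed=0)


class TestKunchevaIndex:
    def test_identical_sets_score_one(self):
        assert kuncheva_index({1, 2, 3}, {1, 2, 3}, 10) == pytest.approx(1.0)

    def test_disjoint_pair_worked_example(self):
        assert kuncheva_index({0, 1}, {2, 3}, 10) == pytest.approx(-0.25)

    def test_partial_overlap_worked_example(self):
        a = set(range(10))
        b = set(range(5, 15))
        assert kuncheva_index(a, b, 100) == pytest.approx(4 / 9)

    def test_unequal_sizes_rejected(self):
        with pytest.raises(ValueError):
            kuncheva_index({1}, {1, 2}, 10)

    @pytest.mark.parametrize("s", [0, 5])
    def test_degenerate_sizes_rejected(self, s):
        with pytest.raises(ValueError):
            kuncheva_index(set(range(s)), set(range(s)), 5)

    def test_bounded_in_minus_one_one(self, rng):
        for _ in range(100):
            p = int(rng.integers(3, 30))
            s = int(rng.integers(1, p))
            a = set(rng.choice(p, s, replace=False).tolist())
            b = set(rng.choice(p, s, replace=False).tolist())
            assert -1.0 - 1e-12 <= kuncheva_index(a, b, p) <= 1.0 + 1e-12


class TestAverageConsistency:
    def test_identical_sets_give_one(self):
        assert average_consistency([{1, 2}] * 6, 10) == pytest.approx(1.0)

    def test_two_sets_equal_single_pair(self):
        a, b = {0, 1, 2}, {2, 3, 4}
        assert average_consistency([a, b], 20) == pytest.approx(
            kuncheva_index(a, b, 20)
        )

    def test_three_sets_hand_computed_mean(self):
        sets = [{0, 1}, {1, 2}, {0, 3}]
        expected = np.mean(
            [
                kuncheva_index(sets[0], sets[1], 8),
                kuncheva_index(sets[0], sets[2], 8),
                kuncheva_index(sets[1], sets[2], 8),
            ]
        )
        assert average_consistency(sets, 8) == pytest.approx(expected)

    def test_pair_count(self):
        vals = pairwise_kuncheva([{0, 1}] * 20, 10)
        assert vals.size == 20 * 19 // 2


class TestNCC:
    def test_single_sample_centroids(self):
        table = make_labeled_table(p=3, n=4, n_pos=2, seed=0)
        sub = table.subset_samples([0, 2])
        model = fit_ncc(sub, "l2")
        np.testing.assert_allclose(model.centroids[0], sub.values[:, 0])
        np.testing.assert_allclose(model.centroids[1], sub.values[:, 1])

    def test_centroid_is_class_mean(self):
        values = np.array([[0.0, 2.0, 5.0], [0.0, 2.0, 1.0]])
        table = AbundanceTable(values, ["a", "b"], ["s1", "s2", "s3"],
                               {"s1": "x", "s2": "x", "s3": "y"})
        model = fit_ncc(table, "l1")
        np.testing.assert_allclose(model.centroids[0], [1.0, 1.0])

    def test_prediction_worked_example(self):
        model = CentroidModel(classes=["c1", "c2"],
                              centroids=np.array([[0.0, 0.0], [4.0, 0.0]]),
                              norm="l1")
        assert predict_ncc(model, np.array([1.0, 3.0])) == "c1"
        model_l2 = CentroidModel(classes=["c1", "c2"],
                                 centroids=np.array([[0.0, 0.0], [4.0, 0.0]]),
                                 norm="l2")
        assert predict_ncc(model_l2, np.array([1.0, 3.0])) == "c1"

    def test_tie_goes_to_first_class(self):
        model = CentroidModel(classes=["first", "second"],
                              centroids=np.array([[0.0], [2.0]]), norm="l2")
        assert predict_ncc(model, np.array([1.0])) == "first"

    def test_dimension_mismatch(self):
        model = CentroidModel(classes=["a", "b"],
                              centroids=np.zeros((2, 3)), norm="l2")
        with pytest.raises(ValueError):
            predict_ncc(model, np.zeros(2))


class TestClassificationMetrics:
    def test_perfect_prediction(self):
        assert classification_metrics(5, 5, 0, 0) == (1.0, 1.0, 1.0)

    def test_worked_example(self):
        acc, sens, spec = classification_metrics(3, 4, 2, 1)
        assert (acc, sens, spec) == pytest.approx((0.7, 0.75, 2 / 3))

    def test_empty_positive_class_gives_nan_sensitivity(self):
        acc, sens, spec = classification_metrics(0, 10, 0, 0)
        assert acc == 1.0 and spec == 1.0 and np.isnan(sens)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            classification_metrics(-1, 0, 0, 2)


def constant_detector(table):
    """Always ranks OTUs in their input order (scores p, p-1, ..., 1)."""
    p = table.p
    S = np.arange(p, 0, -1, dtype=float)[:, None] * np.ones((1, table.n))
    return rank_markers(S, table.otu_ids)


def random_detector(table, salt=0):
    gen = np.random.default_rng(abs(hash((tuple(table.sample_ids), salt))) % 2**31)
    S = gen.uniform(0, 1, (table.p, 1)) * np.ones((1, table.n))
    return rank_markers(S, table.otu_ids)


class TestRunProtocol:
    def test_constant_detector_perfect_stability(self):
        table = make_labeled_table(p=8, n=20, n_pos=8, seed=5)
        cfg = ProtocolConfig(m=3, K=10, seed=1, positive_label="disease")
        stability, classification = run_protocol(table, constant_detector, cfg)
        assert stability.ki_values.size == 10 * 9 // 2
        assert stability.c_avg == pytest.approx(1.0)
        # constant detector also fixes the rank matrix
        assert np.all(stability.rank_matrix == [1, 2, 3])

    def test_protocol_deterministic_given_seed(self):
        table = make_labeled_table(p=8, n=20, n_pos=8, seed=5)
        cfg = ProtocolConfig(m=3, K=6, seed=9, positive_label="disease")
        s1, c1 = run_protocol(table, random_detector, cfg)
        s2, c2 = run_protocol(table, random_detector, cfg)
        np.testing.assert_array_equal(s1.ki_values, s2.ki_values)
        np.testing.assert_array_equal(s1.rank_matrix, s2.rank_matrix)
        pd.testing.assert_frame_equal(c1.per_iteration, c2.per_iteration)
        pd.testing.assert_frame_equal(c1.summary, c2.summary)

    def test_three_subsample_consistency_matches_hand_mean(self):
        table = make_labeled_table(p=10, n=20, n_pos=10, seed=2)
        cfg = ProtocolConfig(m=4, K=3, seed=4, classifier_norms=(),
                             positive_label=None)
        stability, _ = run_protocol(table, random_detector, cfg)
        assert stability.ki_values.size == 3
        assert stability.c_avg == pytest.approx(stability.ki_values.mean())

    def test_failing_detector_aborts(self):
        table = make_labeled_table(p=6, n=20, n_pos=10, seed=0)

        def broken(table):
            raise RuntimeError("boom")

        cfg = ProtocolConfig(m=2, K=10, seed=0, classifier_norms=())
        # the reference run on the full table already fails
        with pytest.raises(Exception):
            run_protocol(table, broken, cfg)

        calls = {"k": 0}

        def flaky(t):
            calls["k"] += 1
            if calls["k"] > 1:  # fail on every subsample, keep the reference run
                raise RuntimeError("boom")
            return constant_detector(t)

        with pytest.raises(ProtocolError, match="1%"):
            run_protocol(table, flaky, cfg)

    def test_positive_label_required_for_classification(self):
        table = make_labeled_table(p=6, n=20, n_pos=10, seed=0)
        cfg = ProtocolConfig(m=2, K=4, seed=0)
        with pytest.raises(ProtocolError, match="positive_label"):
            run_protocol(table, constant_detector, cfg)

    def test_confusion_counts_cover_test_set(self):
        table = make_labeled_table(p=8, n=20, n_pos=8, seed=5)
        cfg = ProtocolConfig(m=3, K=5, seed=3, positive_label="disease")
        _, classification = run_protocol(table, constant_detector, cfg)
        counts = classification.per_iteration[["tp", "tn", "fp", "fn"]].sum(axis=1)
        assert (counts == 4).all()  # n=20, r=0.8 -> 4 test samples
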