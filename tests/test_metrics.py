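import numpy as np
import pytest

from ppisign import (
    LabelMatrix,
    exact_match_ratio,
    label_prf,
    macro_f,
    micro_f,
    per_class_report,
)
from helpers import random_label_matrix

A, I = "A", "I"


def brute_force_metrics(labels, true_sets, pred_sets):
    """From-definition recount, independent of the vectorized implementation."""
    n = len(true_sets)
    exact = sum(
        1 for t, p in zip(true_sets, pred_sets)
        if (t & set(labels)) == (p & set(labels))
    ) / n
    per_label = {}
    confusion = {}
    for lab in labels:
        tp = sum(1 for t, p in zip(true_sets, pred_sets) if lab in t and lab in p)
        fp = sum(1 for t, p in zip(true_sets, pred_sets) if lab not in t and lab in p)
        fn = sum(1 for t, p in zip(true_sets, pred_sets) if lab in t and lab not in p)
        prec = tp / (tp + fp) if tp + fp else 0.0
        rec = tp / (tp + fn) if tp + fn else 0.0
        f = 2 * prec * rec / (prec + rec) if prec + rec else 0.0
        per_label[lab] = (prec, rec, f)
        confusion[lab] = (tp, fp, fn)
    mac = sum(v[2] for v in per_label.values()) / len(labels)
    tp = sum(c[0] for c in confusion.values())
    fp = sum(c[1] for c in confusion.values())
    fn = sum(c[2] for c in confusion.values())
    prec = tp / (tp + fp) if tp + fp else 0.0
    rec = tp / (tp + fn) if tp + fn else 0.0
    mic = 2 * prec * rec / (prec + rec) if prec + rec else 0.0
    return exact, per_label, mac, mic, confusion


@pytest.fixture
def two_label_matrix():
    # true: inst1 {1}, inst2 {1,2}; pred: inst1 {1,2}, inst2 {2}
    return LabelMatrix.from_label_sets(
        ("1", "2"), [{"1"}, {"1", "2"}], [{"1", "2"}, {"2"}]
    )


class TestExactMatchRatio:
    def test_half_match(self):
        M = LabelMatrix.from_label_sets((A, I), [{A}, {I}], [{A}, {A}])
        assert exact_match_ratio(M) == 0.5

    def test_identity_prediction(self):
        M = LabelMatrix.from_label_sets((A, I), [{A}, {I}], [{A}, {I}])
        assert exact_match_ratio(M) == 1.0

    def test_disjoint_prediction(self):
        M = LabelMatrix.from_label_sets((A, I), [{A}, {A}], [{I}, {I}])
        assert exact_match_ratio(M) == 0.0

    def test_zero_instances_fatal(self):
        M = LabelMatrix(labels=(A,), Y=np.zeros((0, 1)), Yhat=np.zeros((0, 1)))
        with pytest.raises(ValueError):
            exact_match_ratio(M)


class TestLabelPRF:
    def test_label_1_counts(self, two_label_matrix):
        p, r, f = label_prf(two_label_matrix, "1")
        assert (p, r) == (1.0, 0.5)
        assert f == pytest.approx(2 / 3)

    def test_label_2_counts(self, two_label_matrix):
        p, r, f = label_prf(two_label_matrix, "2")
        assert (p, r) == (0.5, 1.0)
        assert f == pytest.approx(2 / 3)

    def test_never_true_never_predicted_is_zero(self):
        M = LabelMatrix.from_label_sets((A, I), [{A}, {A}], [{A}, {A}])
        assert label_prf(M, I) == (0.0, 0.0, 0.0)


class TestAverages:
    def test_macro_is_mean_of_per_label_f(self, two_label_matrix):
        assert macro_f(two_label_matrix) == pytest.approx(2 / 3)

    def test_micro_from_pooled_counts(self, two_label_matrix):
        # pooled TP=2, FP=1, FN=1
        assert micro_f(two_label_matrix) == pytest.approx(2 / 3)

    def test_perfect_prediction(self):
        M = LabelMatrix.from_label_sets((A, I), [{A, I}], [{A, I}])
        assert macro_f(M) == micro_f(M) == 1.0

    def test_single_label_macro_equals_label_f(self):
        M = LabelMatrix.from_label_sets((A,), [{A}, {A}], [{A}, set()])
        assert macro_f(M) == pytest.approx(label_prf(M, A)[2])

    def test_all_empty_predictions_zero(self):
        M = LabelMatrix.from_label_sets((A, I), [{A}, {I}], [set(), set()])
        assert micro_f(M) == 0.0


class TestReport:
    def test_report_consistent_with_individual_ops(self, two_label_matrix):
        rep = per_class_report(two_label_matrix)
        assert rep.exact_match_ratio == exact_match_ratio(two_label_matrix)
        assert rep.macro_f == macro_f(two_label_matrix)
        assert rep.micro_f == micro_f(two_label_matrix)
        for lab in two_label_matrix.labels:
            assert rep.per_label[lab] == label_prf(two_label_matrix, lab)

    def test_single_correct_instance_all_ones(self):
        M = LabelMatrix.from_label_sets((A,), [{A}], [{A}])
        rep = per_class_report(M)
        assert rep.exact_match_ratio == rep.macro_f == rep.micro_f == 1.0

    def test_micro_recomputable_from_confusion_counts(self, rng):
        labels, ts, ps = random_label_matrix(rng)
        rep = per_class_report(LabelMatrix.from_label_sets(labels, ts, ps))
        tp = sum(c[0] for c in rep.confusion_counts.values())
        fp = sum(c[1] for c in rep.confusion_counts.values())
        fn = sum(c[2] for c in rep.confusion_counts.values())
        denom = 2 * tp + fp + fn
        expected = 2 * tp / denom if denom else 0.0
        assert rep.micro_f == pytest.approx(expected)

    def test_tsv_has_one_row_per_label_plus_summaries(self, two_label_matrix):
        rep = per_class_report(two_label_matrix)
        lines = rep.to_tsv().strip().split("\n")
        assert len(lines) == 1 + len(rep.labels) + 3


class TestAgainstBruteForce:
    def test_random_matrices_match_recount(self, rng):
        for _ in range(200):
            labels, ts, ps = random_label_matrix(rng)
            M = LabelMatrix.from_label_sets(labels, ts, ps)
            exact, per_label, mac, mic, confusion = brute_force_metrics(
                labels, ts, ps
            )
            rep = per_class_report(M)
            assert rep.exact_match_ratio == pytest.approx(exact)
            assert rep.macro_f == pytest.approx(mac)
            assert rep.micro_f == pytest.approx(mic)
            for lab in labels:
                assert rep.per_label[lab] == pytest.approx(per_label[lab])
                assert rep.confusion_counts[lab] == confusion[lab]

    def test_permuting_instances_leaves_metrics_unchanged(self, rng):
        labels, ts, ps = random_label_matrix(rng, n_max=30)
        perm = rng.permutation(len(ts))
        r1 = per_class_report(LabelMatrix.from_label_sets(labels, ts, ps))
        r2 = per_class_report(
            LabelMatrix.from_label_sets(
                labels, [ts[i] for i in perm], [ps[i] for i in perm]
            )
        )
        assert r1.exact_match_ratio == r2.exact_match_ratio
        assert r1.macro_f == r2.macro_f
        assert r1.micro_f == r2.micro_f

    def test_macro_bounded_by_per_label_extremes(self, rng):
        for _ in range(50):
            labels, ts, ps = random_label_matrix(rng)
            M = LabelMatrix.from_label_sets(labels, ts, ps)
            fs = [label_prf(M, lab)[2] for lab in labels]
            assert min(fs) - 1e-12 <= macro_f(M) <= max(fs) + 1e-12


class TestValidation:
    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="shape mismatch"):
            LabelMatrix(labels=(A,), Y=np.zeros((2, 1)), Yhat=np.zeros((3, 1)))

    def test_nonbinary_rejected(self):
        with pytest.raises(ValueError, match="binary"):
            LabelMatrix(labels=(A,), Y=np.full((2, 1), 2), Yhat=np.zeros((2, 1)))

    def test_instance_without_true_label_rejected(self):
        with pytest.raises(ValueError, match="at least one true label"):
            LabelMatrix.from_label_sets((A,), [set()], [{A}])
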