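"""Confusion counts, precision/recall/FPR, MCC, sweeps, and majority vote."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.metrics import confusion_matrix, matthews_corrcoef

from litrank.evaluation import (ConfusionCounts, confusion, majority_vote, mcc,
                                precision_recall_fpr, read_truth_tsv, sweep,
                                write_curve_tsv)
from litrank.pipeline import RankedResult


def scored(pairs):
    """[(pmid, score)] -> RankedResult list (assignment/rank irrelevant here)."""
    return [RankedResult(p, s, "A" if s > 0.5 else "B", i + 1)
            for i, (p, s) in enumerate(pairs)]


def make_results(tp, fp, tn, fn, threshold=0.5):
    """Construct scores/truth realizing given confusion counts at a threshold."""
    results, truth, pmid = [], {}, 0
    for n, score, label in ((tp, 0.9, "A"), (fp, 0.9, "B"),
                            (tn, 0.1, "B"), (fn, 0.1, "A")):
        for _ in range(n):
            pmid += 1
            results.append(RankedResult(pmid, score, "A" if score > threshold else "B", 1))
            truth[pmid] = label
    return results, truth


class TestConfusion:
    def test_matches_printed_worked_example(self):
        # curated truth 166 A / 50 B with 24 FP and 4 FN
        results, truth = make_results(tp=162, fp=24, tn=26, fn=4)
        c = confusion(results, truth, 0.5)
        assert (c.TP, c.FP, c.TN, c.FN) == (162, 24, 26, 4)
        assert c.total == 216

    def test_everything_scored_high(self):
        results, truth = make_results(tp=10, fp=10, tn=0, fn=0)
        c = confusion(results, truth, 0.5)
        assert c.FN == 0 and c.FP == 10

    def test_empty_results(self):
        assert confusion([], {}, 0.5) == ConfusionCounts(0, 0, 0, 0)

    def test_missing_truth_label_raises(self):
        with pytest.raises(KeyError):
            confusion(scored([(1, 0.9)]), {2: "A"}, 0.5)

    def test_matches_sklearn_confusion_matrix(self):
        results, truth = make_results(tp=7, fp=3, tn=11, fn=5)
        c = confusion(results, truth, 0.5)
        y_true = [1 if truth[r.pmid] == "A" else 0 for r in results]
        y_pred = [1 if r.score > 0.5 else 0 for r in results]
        tn, fp, fn, tp = confusion_matrix(y_true, y_pred).ravel()
        assert (c.TP, c.FP, c.TN, c.FN) == (tp, fp, tn, fn)


class TestRatios:
    def test_worked_example_precision(self):
        c = ConfusionCounts(162, 24, 26, 4)
        precision, recall, fpr = precision_recall_fpr(c)
        assert precision == pytest.approx(162 / 186)
        assert round(precision, 2) == 0.87
        assert c.accuracy == pytest.approx(188 / 216)

    def test_all_assigned_a_on_balanced_truth(self):
        c = ConfusionCounts(TP=50, FP=50, TN=0, FN=0)
        precision, recall, _ = precision_recall_fpr(c)
        assert precision == 0.5 and recall == 1.0

    def test_undefined_ratios_are_none_not_zero(self):
        precision, recall, fpr = precision_recall_fpr(ConfusionCounts(0, 0, 10, 0))
        assert precision is None and recall is None and fpr == 0.0


class TestMcc:
    def test_worked_example_value(self):
        assert mcc(ConfusionCounts(162, 24, 26, 4)) == pytest.approx(0.6, abs=0.05)

    @pytest.mark.parametrize("c,expected", [
        (ConfusionCounts(10, 0, 10, 0), 1.0),
        (ConfusionCounts(0, 10, 0, 10), -1.0),
        (ConfusionCounts(0, 0, 0, 0), 0.0),
        (ConfusionCounts(5, 0, 0, 0), 0.0),  # zero denominator convention
    ])
    def test_limits(self, c, expected):
        assert mcc(c) == expected

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(st.tuples(*[st.integers(min_value=0, max_value=40)] * 4))
    def test_against_sklearn_and_swap_symmetry(self, counts):
        tp, fp, tn, fn = counts
        c = ConfusionCounts(tp, fp, tn, fn)
        if c.total:
            y_true = [1] * tp + [0] * fp + [0] * tn + [1] * fn
            y_pred = [1] * tp + [1] * fp + [0] * tn + [0] * fn
            assert mcc(c) == pytest.approx(matthews_corrcoef(y_true, y_pred),
                                           abs=1e-12)
        # swapping labels and predictions together leaves MCC unchanged
        assert mcc(c) == pytest.approx(mcc(ConfusionCounts(tn, fn, tp, fp)))


class TestSweep:
    def test_rows_match_single_threshold_recounts(self):
        results, truth = make_results(tp=162, fp=24, tn=26, fn=4)
        curve = sweep(results, truth, [0.0, 0.5, 1.0])
        assert len(curve) == 3
        at_half = curve[1]
        assert at_half.precision == pytest.approx(162 / 186)
        assert at_half.mcc_times_100 == pytest.approx(100 * mcc(
            ConfusionCounts(162, 24, 26, 4)))

    def test_threshold_zero_on_balanced_truth(self):
        results, truth = make_results(tp=20, fp=0, tn=20, fn=0)
        row = sweep(results, truth, [0.0])[0]
        assert row.precision == 0.5 and row.recall == 1.0

    def test_threshold_above_max_score_gives_zero_recall(self):
        results, truth = make_results(tp=5, fp=5, tn=5, fn=5)
        row = sweep(results, truth, [0.99])[0]
        assert row.recall == 0.0 and row.precision is None

    def test_unsorted_thresholds_rejected(self):
        results, truth = make_results(tp=1, fp=1, tn=1, fn=1)
        with pytest.raises(ValueError):
            sweep(results, truth, [0.5, 0.1])

    @settings(deadline=None, derandomize=True, max_examples=40)
    @given(st.lists(st.tuples(st.floats(min_value=0, max_value=1),
                              st.booleans()), min_size=1, max_size=40))
    def test_recall_and_fpr_monotone_nonincreasing(self, data):
        results = scored([(i, s) for i, (s, _) in enumerate(data)])
        truth = {i: ("A" if is_a else "B") for i, (_, is_a) in enumerate(data)}
        curve = sweep(results, truth)
        recalls = [pt.recall for pt in curve if pt.recall is not None]
        fprs = [pt.fpr for pt in curve if pt.fpr is not None]
        assert all(a >= b for a, b in zip(recalls, recalls[1:]))
        assert all(a >= b for a, b in zip(fprs, fprs[1:]))


class TestMajorityVote:
    def test_disagreement_flags_ambiguity(self):
        voted = majority_vote({1: ["A", "A", "B"], 2: ["A", "A", "A"]})
        assert voted[1] == ("A", True)
        assert voted[2] == ("A", False)

    def test_even_annotator_count_rejected(self):
        with pytest.raises(ValueError):
            majority_vote({1: ["A", "B"]})

    def test_curation_arithmetic_consistency(self):
        """122 unanimous-A + 30 unanimous-B + 64 split (44 toward A, 20
        toward B) must yield a 166/50 majority split with 64 ambiguous."""
        annotations, pmid = {}, 0
        for n, labels in ((122, ["A", "A", "A"]), (30, ["B", "B", "B"]),
                          (44, ["A", "A", "B"]), (20, ["B", "B", "A"])):
            for _ in range(n):
                pmid += 1
                annotations[pmid] = labels
        voted = majority_vote(annotations)
        assert sum(lab == "A" for lab, _ in voted.values()) == 166
        assert sum(lab == "B" for lab, _ in voted.values()) == 50
        assert sum(amb for _, amb in voted.values()) == 64


def test_truth_tsv_single_and_curation_formats(tmp_path):
    single = tmp_path / "truth1.tsv"
    single.write_text("1\tA\n2\tB\n")
    labels, ambiguity = read_truth_tsv(single)
    assert labels == {1: "A", 2: "B"} and not any(ambiguity.values())

    curated = tmp_path / "truth3.tsv"
    curated.write_text("1\tA\tA\tB\n2\tB\tB\tB\n")
    labels, ambiguity = read_truth_tsv(curated)
    assert labels == {1: "A", 2: "B"}
    assert ambiguity == {1: True, 2: False}


def test_curve_tsv_writes_undefined_for_none(tmp_path):
    results, truth = make_results(tp=0, fp=0, tn=3, fn=0)
    path = tmp_path / "curve.tsv"
    write_curve_tsv(sweep(results, truth, [0.5]), path)
    assert "undefined" in path.read_text()
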