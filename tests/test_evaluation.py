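import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from aaaquant.evaluation import (
    ClassMetrics,
    ClassReport,
    ConfusionMatrix,
    aggregate,
    class_report,
    confusion,
    correct_background,
    dice_from_jaccard,
    jaccard_from_dice,
)
from aaaquant.classes import N_CLASSES


# Published validation-set classification report for the AAA wall
# segmentation model (per-class precision, recall, F1, Jaccard, pixel
# support); used to check the aggregation and correction conventions.
VALIDATION_ROWS = {
    "ignore": ClassMetrics(0.091, 0.070, 0.079, 0.041, 41_672_692),
    "zone1": ClassMetrics(0.766, 0.903, 0.829, 0.708, 265_953_620),
    "zone2": ClassMetrics(0.858, 0.796, 0.826, 0.704, 306_283_491),
    "thrombus": ClassMetrics(0.969, 0.887, 0.926, 0.862, 145_997_791),
    "background": ClassMetrics(0.312, 0.984, 0.474, 0.310, 760_249_363),
}


@pytest.fixture()
def validation_report() -> ClassReport:
    return ClassReport(dict(VALIDATION_ROWS))


class TestDiceJaccardConversion:
    @pytest.mark.parametrize("d,j", [(0.7, 0.538), (1.0, 1.0), (0.0, 0.0)])
    def test_known_points(self, d, j):
        assert round(jaccard_from_dice(d), 3) == j

    @given(st.floats(0, 1))
    @settings(max_examples=100, deadline=None)
    def test_mutual_inverses(self, d):
        assert dice_from_jaccard(jaccard_from_dice(d)) == pytest.approx(d, abs=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            jaccard_from_dice(1.2)


class TestConfusion:
    def test_perfect_prediction_is_diagonal(self, rng):
        labels = rng.integers(0, N_CLASSES, size=(20, 20))
        cm = confusion(labels, labels)
        assert np.array_equal(np.diag(np.diag(cm.counts)), cm.counts)
        norm = cm.normalized()
        present = cm.support > 0
        assert np.allclose(np.diag(norm)[present], 1.0)

    def test_two_class_hand_count(self):
        truth = np.array([[0, 0, 1], [1, 1, 0]])
        pred = np.array([[0, 1, 1], [1, 0, 0]])
        cm = confusion(pred, truth, class_order=("a", "b"))
        assert cm.counts.tolist() == [[2, 1], [1, 2]]

    def test_matches_per_pixel_loop_oracle(self, rng):
        truth = rng.integers(0, N_CLASSES, size=(15, 17))
        pred = rng.integers(0, N_CLASSES, size=(15, 17))
        cm = confusion(pred, truth)
        expected = np.zeros((N_CLASSES, N_CLASSES), dtype=int)
        for i in range(15):
            for j in range(17):
                expected[truth[i, j], pred[i, j]] += 1
        assert np.array_equal(cm.counts, expected)

    def test_agrees_with_sklearn(self, rng):
        from sklearn.metrics import confusion_matrix as sk_confusion

        truth = rng.integers(0, N_CLASSES, size=400)
        pred = rng.integers(0, N_CLASSES, size=400)
        cm = confusion(pred.reshape(20, 20), truth.reshape(20, 20))
        assert np.array_equal(cm.counts,
                              sk_confusion(truth, pred, labels=range(N_CLASSES)))

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            confusion(np.zeros((2, 2), int), np.zeros((3, 3), int))

    def test_row_normalization_sums_to_one(self, rng):
        truth = rng.integers(0, N_CLASSES, size=(30, 30))
        pred = rng.integers(0, N_CLASSES, size=(30, 30))
        rows = confusion(pred, truth).normalized().sum(axis=1)
        assert np.allclose(rows, 1.0)


class TestClassReport:
    def test_perfect_prediction_metrics_all_one(self, rng):
        labels = rng.integers(0, 3, size=(10, 10))
        cm = confusion(labels, labels, class_order=("a", "b", "c"))
        rep = class_report(cm)
        for m in rep.per_class.values():
            if m.support:
                assert (m.precision, m.recall, m.f1, m.jaccard) == (1, 1, 1, 1)

    def test_definitional_arithmetic(self):
        # one TP, one FP, one FN for class 0
        counts = np.array([[1, 1], [1, 1]])
        rep = class_report(ConfusionMatrix(counts, ("a", "b")))
        m = rep.per_class["a"]
        assert (m.precision, m.recall, m.f1) == (0.5, 0.5, 0.5)
        assert m.jaccard == pytest.approx(1 / 3)

    @given(st.integers(0, 10_000), st.integers(0, 10_000), st.integers(0, 10_000))
    @settings(max_examples=100, deadline=None)
    def test_jaccard_equals_f1_conversion_identity(self, tp, fp, fn):
        """J = F/(2-F) holds exactly for metrics from the same counts."""
        if tp + fp + fn == 0:
            return
        counts = np.array([[tp, fn], [fp, 0]])
        m = class_report(ConfusionMatrix(counts, ("pos", "neg"))).per_class["pos"]
        assert m.jaccard == pytest.approx(jaccard_from_dice(m.f1), abs=1e-12)

    def test_zero_denominator_reports_zero(self):
        counts = np.array([[0, 0], [5, 0]])  # class b never predicted correctly
        rep = class_report(ConfusionMatrix(counts, ("a", "b")))
        assert rep.per_class["b"].f1 == 0.0


class TestAggregation:
    """The published report aggregates reconstruct from the per-class rows."""

    def test_macro_average_all_classes(self, validation_report):
        agg = aggregate(validation_report, "macro")
        assert round(agg.precision, 3) == 0.599
        assert round(agg.recall, 3) == 0.728
        assert round(agg.f1, 3) == 0.627
        assert round(agg.jaccard, 3) == 0.456

    def test_macro_average_excluding_ignore(self, validation_report):
        agg = aggregate(validation_report, "macro", exclude={"ignore"})
        assert round(agg.precision, 3) == 0.726

    def test_weighted_average_all_classes(self, validation_report):
        agg = aggregate(validation_report, "weighted")
        # aggregating the rounded per-class rows reproduces the published
        # aggregates to +/- 0.001 (they were computed from full precision)
        assert agg.f1 == pytest.approx(0.639, abs=1e-3)
        assert round(agg.jaccard, 3) == 0.470

    def test_exclusion_equals_report_without_class(self, validation_report):
        without = ClassReport({k: v for k, v in VALIDATION_ROWS.items() if k != "ignore"})
        for mode in ("macro", "weighted"):
            a = aggregate(validation_report, mode, exclude={"ignore"})
            b = aggregate(without, mode)
            assert a == b

    def test_empty_inclusion_set_rejected(self, validation_report):
        with pytest.raises(ValueError):
            aggregate(validation_report, "macro", exclude=set(VALIDATION_ROWS))

    def test_zero_support_class_dropped_with_warning(self):
        rows = {"a": ClassMetrics(0.5, 0.5, 0.5, 1 / 3, 100),
                "b": ClassMetrics(0.0, 0.0, 0.0, 0.0, 0)}
        with pytest.warns(UserWarning, match="zero-support"):
            agg = aggregate(ClassReport(rows), "macro")
        assert agg.precision == 0.5

    def test_mean_jaccard_convention_available(self, validation_report):
        rep = ClassReport(dict(VALIDATION_ROWS), jaccard_convention="mean")
        agg = aggregate(rep, "macro")
        expected = np.mean([m.jaccard for m in VALIDATION_ROWS.values()])
        assert agg.jaccard == pytest.approx(expected)


class TestBackgroundCorrection:
    def test_corrected_background_row(self, validation_report):
        corrected = correct_background(validation_report, 0.980)
        bg = corrected.per_class["background"]
        assert round(bg.f1, 3) == 0.982
        assert round(bg.jaccard, 3) == 0.965
        assert bg.recall == 0.984  # recall untouched

    def test_identity_when_estimate_equals_original(self, validation_report):
        same = correct_background(validation_report,
                                  validation_report.per_class["background"].precision)
        bg = same.per_class["background"]
        orig = validation_report.per_class["background"]
        assert bg.precision == orig.precision
        assert bg.f1 == pytest.approx(orig.f1, abs=1e-3)

    def test_corrected_weighted_aggregates(self, validation_report):
        corrected = correct_background(validation_report, 0.980)
        agg_all = aggregate(corrected, "weighted")
        assert agg_all.precision == pytest.approx(0.893, abs=1e-3)
        assert round(agg_all.jaccard, 3) == 0.808
        agg_excl = aggregate(corrected, "weighted", exclude={"ignore"})
        assert round(100 * agg_excl.jaccard, 1) == 84.6

    def test_invalid_estimate_rejected(self, validation_report):
        with pytest.raises(ValueError):
            correct_background(validation_report, 0.0)


class TestReportTable:
    def test_csv_roundtrip_has_table_columns(self, validation_report, tmp_path):
        import pandas as pd

        path = tmp_path / "report.csv"
        validation_report.to_csv(path)
        frame = pd.read_csv(path, index_col=0)
        assert list(frame.columns) == [
            "Precision", "Recall", "F1-score", "Jaccard index", "Support"
        ]
        assert frame.loc["zone1", "Jaccard index"] == 0.708

    def test_confusion_heatmap_renders(self, rng, tmp_path):
        truth = rng.integers(0, N_CLASSES, size=(20, 20))
        pred = rng.integers(0, N_CLASSES, size=(20, 20))
        out = tmp_path / "cm.png"
        confusion(pred, truth).plot(out)
        assert out.exists()
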