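"""Threshold classification at points and confusion-matrix metrics."""

import numpy as np
import pytest

from grassunmix.accuracy_assessment import (
    UNCLASSIFIED,
    accuracy_metrics,
    confusion_matrix,
    confusion_table,
    predicted_class_at_points,
)
from grassunmix.datasets import load_reference_confusion
from grassunmix.errors import DataError
from grassunmix.types import ConfusionMatrix, FractionStack, ReferencePoints


def stack_of(frac_by_class):
    frac = np.asarray(frac_by_class, dtype=float)[:, None, None]
    return FractionStack(
        fractions=np.tile(frac, (1, 2, 2)),
        class_names=["a", "b", "c"][: frac.shape[0]],
        origin_xy=(0.0, 2.0),
    )


def points_at(stack, n=1):
    return ReferencePoints(
        x=[0.5] * n, y=[0.5] * n, labels=["a"] * n,
        class_list=stack.class_names,
    )


class TestPredictedClass:
    def test_dominant_class_wins_at_half(self):
        stack = stack_of([1.0, 0.0, 0.0])
        assert predicted_class_at_points(stack, points_at(stack), 0.5) == ["a"]

    def test_no_qualifier_is_unclassified(self):
        stack = stack_of([0.4, 0.35, 0.25])
        assert predicted_class_at_points(stack, points_at(stack), 0.5) == [
            UNCLASSIFIED
        ]

    def test_largest_fraction_wins_below_half(self):
        stack = stack_of([0.4, 0.35, 0.25])
        assert predicted_class_at_points(stack, points_at(stack), 0.2) == ["a"]

    def test_tie_breaks_lexicographically(self):
        stack = FractionStack(
            fractions=np.tile(
                np.array([0.5, 0.5])[:, None, None], (1, 2, 2)
            ),
            class_names=["zeta", "alpha"],
            origin_xy=(0.0, 2.0),
        )
        pts = ReferencePoints(
            x=[0.5], y=[0.5], labels=["zeta"], class_list=stack.class_names
        )
        assert predicted_class_at_points(stack, pts, 0.5) == ["alpha"]

    def test_point_outside_extent_reports_index(self):
        stack = stack_of([1.0, 0.0, 0.0])
        pts = ReferencePoints(x=[0.5, 99.0], y=[0.5, 0.5], labels=["a", "a"])
        with pytest.raises(DataError, match=r"\[1\]"):
            predicted_class_at_points(stack, pts, 0.5)

    def test_invalid_pixel_is_unclassified(self):
        stack = stack_of([1.0, 0.0, 0.0])
        stack.pixel_valid[1, 0] = False
        pts = ReferencePoints(x=[0.5], y=[0.5], labels=["a"])
        # (row 1, col 0) is at map y in (0, 1), x in (0, 1)
        assert predicted_class_at_points(
            stack, ReferencePoints(x=[0.5], y=[0.5], labels=["a"]), 0.5
        ) == [UNCLASSIFIED]

    def test_matches_per_point_lookup_oracle(self, noisy_truth):
        from grassunmix.synthetic_scene import sample_reference_points

        stack = noisy_truth.fractions
        pts = sample_reference_points(noisy_truth, 20, purity=0.75, seed=3)
        predicted = predicted_class_at_points(stack, pts, 0.5)
        rows, cols = stack.rowcol_of_xy(pts.x, pts.y)
        for lab, r, c in zip(predicted, rows, cols):
            frac = stack.fractions[:, r, c]
            if frac.max() >= 0.5:
                assert lab == stack.class_names[int(np.argmax(frac))]
            else:
                assert lab == UNCLASSIFIED


class TestConfusionMatrix:
    def test_perfect_labels_are_diagonal(self):
        labels = ["a"] * 3 + ["b"] * 2
        cm = confusion_matrix(labels, labels, ["a", "b"])
        assert np.array_equal(cm.counts, [[3, 0], [0, 2]])

    def test_published_cells_at_half_threshold(self):
        # reconstruct label sequences from the published 50%-threshold cells
        ref_cm = load_reference_confusion(0.5)
        reference, predicted = [], []
        for i, r in enumerate(ref_cm.class_order):
            for j, p in enumerate(ref_cm.class_order):
                reference += [r] * ref_cm.counts[i, j]
                predicted += [p] * ref_cm.counts[i, j]
        cm = confusion_matrix(reference, predicted, ref_cm.class_order)
        assert np.array_equal(
            cm.counts, [[36, 10, 4], [9, 41, 0], [0, 1, 49]]
        )
        assert cm.total == 150

    def test_empty_input_is_zero_matrix(self):
        cm = confusion_matrix([], [], ["a", "b"])
        assert cm.total == 0

    def test_unclassified_counted_separately(self):
        cm = confusion_matrix(
            ["a", "a", "b"], ["a", UNCLASSIFIED, "b"], ["a", "b"]
        )
        assert cm.n_unclassified == 1
        assert cm.total == 2

    def test_unknown_label_is_error(self):
        with pytest.raises(DataError, match="water"):
            confusion_matrix(["a"], ["water"], ["a", "b"])


class TestAccuracyMetrics:
    def test_half_threshold_published_metrics(self):
        cm = load_reference_confusion(0.5)
        overall, users, producers = accuracy_metrics(cm)
        assert overall == pytest.approx(0.84)
        assert users["bare_soil"] == pytest.approx(0.72)
        assert users["grasses"] == pytest.approx(0.82)
        assert users["mixed_forbs"] == pytest.approx(0.98)
        assert producers["bare_soil"] == pytest.approx(36 / 45)
        assert producers["grasses"] == pytest.approx(41 / 52)
        assert producers["mixed_forbs"] == pytest.approx(49 / 53)

    def test_three_quarter_threshold_published_metrics(self):
        cm = load_reference_confusion(0.75)
        overall, users, _ = accuracy_metrics(cm)
        assert overall == pytest.approx(0.60)
        assert users["bare_soil"] == pytest.approx(0.52)
        assert users["grasses"] == pytest.approx(27 / 54)
        assert users["mixed_forbs"] == pytest.approx(0.74)

    def test_identity_matrix_is_perfect(self):
        cm = ConfusionMatrix(counts=np.eye(3, dtype=int) * 5,
                             class_order=["a", "b", "c"])
        overall, users, producers = accuracy_metrics(cm)
        assert overall == 1.0
        assert all(v == 1.0 for v in users.values())
        assert all(v == 1.0 for v in producers.values())

    def test_overall_invariant_to_joint_permutation(self):
        cm = load_reference_confusion(0.5)
        perm = [2, 0, 1]
        permuted = ConfusionMatrix(
            counts=cm.counts[np.ix_(perm, perm)],
            class_order=[cm.class_order[i] for i in perm],
        )
        assert accuracy_metrics(permuted)[0] == accuracy_metrics(cm)[0]

    def test_metrics_bounded_in_unit_interval(self):
        cm = load_reference_confusion(0.75)
        overall, users, producers = accuracy_metrics(cm)
        for v in [overall, *users.values(), *producers.values()]:
            assert 0.0 <= v <= 1.0

    def test_standard_convention_swaps_assignments(self):
        cm = load_reference_confusion(0.5)
        _, users_p, producers_p = accuracy_metrics(cm, "study")
        _, users_s, producers_s = accuracy_metrics(cm, "standard")
        assert users_p == producers_s and producers_p == users_s

    def test_empty_matrix_is_error(self):
        cm = ConfusionMatrix(counts=np.zeros((2, 2), int),
                             class_order=["a", "b"])
        with pytest.raises(DataError):
            accuracy_metrics(cm)

    def test_empty_row_absent_not_zero(self):
        cm = ConfusionMatrix(
            counts=np.array([[5, 0], [0, 0]]), class_order=["a", "b"]
        )
        _, users, _ = accuracy_metrics(cm)
        assert "b" not in users

    def test_table_layout(self):
        table = confusion_table(load_reference_confusion(0.5))
        assert list(table.index) == [
            "bare_soil", "grasses", "mixed_forbs", "Total",
        ]
        assert table.loc["Total", "Total"] == 150
        assert table.attrs["overall_accuracy"] == pytest.approx(0.84)
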