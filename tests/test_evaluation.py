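"""Correspondence mapping and detection / frame-wise metrics."""

import itertools

import numpy as np
import pytest

from hamadl.evaluation import (
    CorrespondenceMatrix,
    correspondence_matrix,
    detection_metrics,
    evaluate_tracks,
    frame_metrics,
    map_labels,
    track_frame_labels,
)
from hamadl.trajectory_io import AnnotationTrack, FrameInterval


def track(*entries):
    return AnnotationTrack([(lab, FrameInterval(s, e)) for lab, s, e in entries])


class TestCorrespondenceMatrix:
    def test_renamed_labels_form_permutation(self):
        gt = track(("A", 0, 9), ("B", 10, 19))
        pred = track(("x", 0, 9), ("y", 10, 19))
        cor = correspondence_matrix(pred, gt)
        assert cor.rows == ["x", "y"] and cor.cols == ["A", "B"]
        assert np.array_equal(cor.counts, [[10, 0], [0, 10]])

    def test_disjoint_intervals_zero_matrix(self):
        gt = track(("A", 0, 9))
        pred = track(("x", 100, 109))
        cor = correspondence_matrix(pred, gt)
        assert cor.counts.sum() == 0

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_per_frame_double_loop(self, seed):
        rng = np.random.default_rng(seed)

        def random_track(labels):
            entries, f = [], 0
            while f < 100:
                d = int(rng.integers(5, 30))
                entries.append((str(rng.choice(labels)), f, min(f + d, 99)))
                f += d + 1
            return track(*entries)

        pred, gt = random_track(["x", "y", "z"]), random_track(["A", "B"])
        cor = correspondence_matrix(pred, gt)
        pl, gl = track_frame_labels(pred), track_frame_labels(gt)
        for i, r in enumerate(cor.rows):
            for j, c in enumerate(cor.cols):
                expected = sum(
                    1 for f in range(100) if pl.get(f) == r and gl.get(f) == c
                )
                assert cor.counts[i, j] == expected


class TestMapLabels:
    def test_recovers_permutation(self):
        gt = track(("A", 0, 9), ("B", 10, 19), ("C", 20, 29))
        pred = track(("c", 20, 29), ("a", 0, 9), ("b", 10, 19))
        mapping = map_labels(correspondence_matrix(pred, gt))
        assert mapping == {"a": "A", "b": "B", "c": "C"}

    def test_majority_co_occurrence_wins(self):
        # a recognized activity coinciding 80% with one label maps to it
        pred = track(("Activity 2 in Zone 1", 0, 99))
        gt = track(("Prepare Drink", 0, 79), ("Other", 80, 99))
        mapping = map_labels(correspondence_matrix(pred, gt))
        assert mapping["Activity 2 in Zone 1"] == "Prepare Drink"

    @pytest.mark.parametrize("shape", [(2, 2), (3, 4), (5, 5), (6, 6)])
    def test_matches_brute_force_permutations(self, shape, rng):
        counts = rng.integers(0, 50, size=shape)
        rows = [f"r{i}" for i in range(shape[0])]
        cols = [f"c{j}" for j in range(shape[1])]
        cor = CorrespondenceMatrix(rows, cols, counts)
        mapping = map_labels(cor)
        got = sum(
            counts[i, cols.index(mapping[r])]
            for i, r in enumerate(rows)
            if mapping[r] != "none"
        )
        n_r, n_c = shape
        best = 0
        for perm in itertools.permutations(range(n_c), min(n_r, n_c)):
            best = max(best, sum(counts[i, j] for i, j in enumerate(perm)))
        assert got == best


class TestDetectionMetrics:
    def test_perfect_prediction_all_ones(self):
        gt = track(("A", 0, 9), ("B", 10, 19), ("A", 30, 49))
        m = detection_metrics(gt, gt, {"A": "A", "B": "B"})
        for cls in ("A", "B"):
            assert m[cls]["precision"] == m[cls]["recall"] == m[cls]["f_score"] == 1.0

    def test_exact_80_percent_overlap_is_fn(self):
        # "higher than 80%" is strict: covering exactly 80 of 100 frames fails
        gt = track(("A", 0, 99))
        pred = track(("A", 0, 79))
        m = detection_metrics(pred, gt, {"A": "A"})
        assert m["A"]["tp"] == 0 and m["A"]["fn"] == 1 and m["A"]["fp"] == 1

    def test_just_over_80_percent_is_tp(self):
        gt = track(("A", 0, 99))
        pred = track(("A", 0, 80))
        m = detection_metrics(pred, gt, {"A": "A"})
        assert m["A"]["tp"] == 1

    def test_hand_enumerated_three_class_fixture(self):
        gt = track(("A", 0, 99), ("B", 100, 199), ("C", 200, 299), ("A", 300, 399))
        pred = track(
            ("A", 0, 95),     # covers 96% of GT A#1 -> TP
            ("B", 100, 150),  # covers 51% of GT B  -> FP + FN
            ("C", 190, 299),  # covers 100% of GT C -> TP
            ("A", 305, 330),  # covers 26% of GT A#2 -> FP + FN
        )
        m = detection_metrics(pred, gt, {c: c for c in "ABC"})
        assert (m["A"]["tp"], m["A"]["fp"], m["A"]["fn"]) == (1, 1, 1)
        assert (m["B"]["tp"], m["B"]["fp"], m["B"]["fn"]) == (0, 1, 1)
        assert (m["C"]["tp"], m["C"]["fp"], m["C"]["fn"]) == (1, 0, 0)
        assert m["A"]["precision"] == pytest.approx(0.5)
        assert m["A"]["recall"] == pytest.approx(0.5)
        assert m["C"]["f_score"] == pytest.approx(1.0)

    def test_one_prediction_validates_one_gt_only(self):
        gt = track(("A", 0, 9), ("A", 10, 19))
        pred = track(("A", 0, 19))  # spans both GT intervals
        m = detection_metrics(pred, gt, {"A": "A"})
        assert m["A"]["tp"] == 1 and m["A"]["fn"] == 1


class TestFrameMetrics:
    def test_perfect_prediction(self):
        gt = track(("A", 0, 9), ("B", 10, 19))
        fa1, f, iou, _ = frame_metrics(gt, gt, {"A": "A", "B": "B"})
        assert fa1 == 1.0 and f == 1.0 and iou == 1.0

    def test_never_matching(self):
        gt = track(("A", 0, 19))
        pred = track(("B", 0, 19))
        fa1, f, iou, _ = frame_metrics(pred, gt, {"B": "B"})
        assert fa1 == 0.0 and iou == 0.0

    def test_twenty_frame_two_class_hand_computed(self):
        # GT: A on frames 0..9, B on 10..19; prediction flips frames 8, 9
        gt = track(("A", 0, 9), ("B", 10, 19))
        pred = track(("A", 0, 7), ("B", 8, 19))
        fa1, f, iou, per_class = frame_metrics(pred, gt, {"A": "A", "B": "B"})
        assert fa1 == pytest.approx(18 / 20, abs=1e-12)
        assert per_class["A"]["precision"] == pytest.approx(1.0)
        assert per_class["A"]["recall"] == pytest.approx(0.8)
        assert per_class["A"]["f_score"] == pytest.approx(8 / 9, abs=1e-12)
        assert per_class["B"]["precision"] == pytest.approx(10 / 12, abs=1e-12)
        assert per_class["B"]["recall"] == pytest.approx(1.0)
        assert f == pytest.approx((8 / 9 + 10 / 11) / 2, abs=1e-12)
        assert iou == pytest.approx((8 / 10 + 10 / 12) / 2, abs=1e-12)

    @pytest.mark.parametrize("seed", range(3))
    def test_iou_bounded_by_precision_and_recall(self, seed):
        rng = np.random.default_rng(seed)

        def random_track(labels):
            entries, f = [], 0
            while f < 200:
                d = int(rng.integers(5, 40))
                entries.append((str(rng.choice(labels)), f, min(f + d, 199)))
                f += d + 1
            return track(*entries)

        gt, pred = random_track(list("ABC")), random_track(list("ABC"))
        _, _, _, per_class = frame_metrics(pred, gt, {c: c for c in "ABC"})
        for m in per_class.values():
            assert m["iou"] <= m["recall"] + 1e-12
            assert m["iou"] <= m["precision"] + 1e-12

    def test_relabeling_invariance(self):
        gt = track(("A", 0, 9), ("B", 10, 19))
        pred = track(("A", 0, 7), ("B", 8, 19))
        base = frame_metrics(pred, gt, {"A": "A", "B": "B"})[:3]
        ren_gt = track(("X", 0, 9), ("Y", 10, 19))
        ren_pred = track(("X", 0, 7), ("Y", 8, 19))
        renamed = frame_metrics(ren_pred, ren_gt, {"X": "X", "Y": "Y"})[:3]
        assert base == renamed

    def test_neutral_excluded_from_averages_counted_in_fa(self):
        gt = track(("A", 0, 9), ("Neutral", 10, 19))
        pred = track(("A", 0, 14), ("B", 15, 19))
        fa1, _, _, per_class = frame_metrics(pred, gt, {"A": "A", "B": "B"})
        assert "Neutral" not in per_class
        assert fa1 == pytest.approx(10 / 20)
        fa1_ex, _, _, _ = frame_metrics(
            pred, gt, {"A": "A", "B": "B"}, include_neutral_in_fa=False
        )
        assert fa1_ex == pytest.approx(10 / 10)


class TestEvaluateTracks:
    def test_end_to_end_identity(self):
        gt = track(("A", 0, 9), ("B", 10, 19))
        report = evaluate_tracks([(gt, gt)])
        assert report.frame_accuracy == 1.0 and report.iou == 1.0
        assert report.f_score == 1.0
        assert report.mapping == {"A": "A", "B": "B"}

    def test_empty_tracks_warn(self):
        with pytest.warns(UserWarning):
            report = evaluate_tracks([(AnnotationTrack([]), AnnotationTrack([]))])
        assert report.frame_accuracy == 0.0
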