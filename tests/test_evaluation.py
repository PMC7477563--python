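import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from reflexloc.data_io import EventAnnotation
from reflexloc.detection import Detection
from reflexloc.evaluation import (
    DEFAULT_FROC_GRID,
    compute_report,
    froc_curve,
    grouped_kfold,
    match_detections,
    temporal_iou,
)


def det(clip, a, b, conf=0.9):
    return Detection(clip, a, b, conf)


def ann(clip, a, b, pid="p1"):
    return EventAnnotation(clip, pid, a, b, 15.0)


def frame_set_iou(a, b):
    """Independent oracle: explicit frame-set intersection over union."""
    sa, sb = set(range(*a)), set(range(*b))
    return len(sa & sb) / len(sa | sb)


class TestTemporalIOU:
    @pytest.mark.parametrize(
        "a,b,expected",
        [
            ((10, 20), (10, 20), 1.0),
            ((0, 10), (10, 20), 0.0),
            ((10, 20), (15, 25), 5 / 15),
            ((0, 1), (0, 2), 0.5),
        ],
    )
    def test_known_values(self, a, b, expected):
        assert temporal_iou(a, b) == pytest.approx(expected)

    def test_symmetry_and_oracle_on_small_grid(self):
        intervals = [(a, b) for a in range(15) for b in range(a + 1, 16)]
        for ia, ib in itertools.product(intervals, repeat=2):
            got = temporal_iou(ia, ib)
            assert got == pytest.approx(frame_set_iou(ia, ib))
            assert got == pytest.approx(temporal_iou(ib, ia))

    def test_empty_interval_rejected(self):
        with pytest.raises(ValueError):
            temporal_iou((5, 5), (0, 3))


class TestMatching:
    def test_single_pair_above_threshold(self):
        m = match_detections([det("c", 10, 20)], [ann("c", 12, 22)], 0.4)
        assert (m.tp, m.fp, m.fn) == (1, 0, 0)
        assert m.pairs[0][2] == pytest.approx(8 / 12)

    def test_same_pair_below_threshold(self):
        m = match_detections([det("c", 10, 20)], [ann("c", 15, 25)], 0.6)
        assert (m.tp, m.fp, m.fn) == (0, 1, 1)

    def test_greedy_matches_best_of_two_detections(self):
        dets = [det("c", 10, 20, 0.9), det("c", 12, 26, 0.8)]
        m = match_detections(dets, [ann("c", 10, 20)], 0.2)
        assert (m.tp, m.fp, m.fn) == (1, 1, 0)
        assert m.pairs[0][0].interval == (10, 20)  # the higher-IOU detection

    def test_matching_is_per_clip(self):
        # identical intervals in different clips must not match
        m = match_detections([det("c1", 10, 20)], [ann("c2", 10, 20)], 0.2)
        assert (m.tp, m.fp, m.fn) == (0, 1, 1)

    def test_count_conservation(self):
        dets = [det("c", 5, 9), det("c", 20, 30), det("c", 50, 60)]
        anns = [ann("c", 6, 10), ann("c", 21, 28)]
        for thr in (0.05, 0.3, 0.6, 0.9):
            m = match_detections(dets, anns, thr)
            assert m.tp + m.fp == len(dets)
            assert m.tp + m.fn == len(anns)

    def test_empty_inputs_zero_counts(self):
        m = match_detections([], [], 0.5)
        assert (m.tp, m.fp, m.fn) == (0, 0, 0)

    def test_bad_threshold_rejected(self):
        with pytest.raises(ValueError):
            match_detections([], [], 0.0)


class TestReport:
    def test_printed_definition_arithmetic(self):
        dets = [det("c", 0, 10), det("c", 20, 30), det("c", 40, 50),
                det("c", 70, 80)]
        anns = [ann("c", 0, 10), ann("c", 20, 30), ann("c", 40, 50),
                ann("c", 90, 99)]
        m = match_detections(dets, anns, 0.5)
        r = compute_report(m, fps=15)
        assert (m.tp, m.fp, m.fn) == (3, 1, 1)
        assert r.precision == pytest.approx(0.75)
        assert r.recall == pytest.approx(0.75)
        assert r.f1 == pytest.approx(0.75)
        assert r.miss_rate == pytest.approx(0.25)

    def test_start_error_in_seconds(self):
        m = match_detections([det("c", 32, 40)], [ann("c", 30, 40)], 0.5)
        r = compute_report(m, fps=15)
        assert r.start_error_mean_s == pytest.approx(2 / 15)
        assert r.end_error_mean_s == pytest.approx(0.0)

    def test_no_true_positives_degenerate(self):
        m = match_detections([det("c", 0, 5)], [ann("c", 50, 60)], 0.5)
        r = compute_report(m, fps=15)
        assert r.precision == 0 and r.recall == 0 and r.f1 == 0
        assert r.miss_rate == 1.0
        assert r.n_pairs == 0
        assert np.isnan(r.start_error_mean_s)

    def test_f1_harmonic_mean_bounds(self):
        dets = [det("c", 0, 10), det("c", 30, 40), det("c", 60, 70)]
        anns = [ann("c", 0, 10), ann("c", 100, 110)]
        for thr in (0.1, 0.5):
            r = compute_report(match_detections(dets, anns, thr), fps=15)
            assert r.f1 <= min(2 * r.precision, 2 * r.recall) + 1e-12
            assert (r.f1 == 0) == (r.tp == 0)


class TestFROC:
    def test_default_grid_has_19_points(self):
        assert len(DEFAULT_FROC_GRID) == 19
        assert DEFAULT_FROC_GRID[0] == pytest.approx(0.05)
        assert DEFAULT_FROC_GRID[-1] == pytest.approx(0.95)

    def test_perfect_overlap_scores_one_near_zero_threshold(self):
        dets = [det("c", 10, 20)]
        anns = [ann("c", 10, 20)]
        curve = froc_curve(dets, anns, [0.05])
        assert curve[0][1] == pytest.approx(1.0)

    @settings(deadline=None, max_examples=20, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_f1_non_increasing_in_threshold(self, seed):
        rng = np.random.default_rng(seed)
        anns, dets = [], []
        for i in range(6):
            s = int(rng.integers(0, 80))
            d = int(rng.integers(1, 13))
            anns.append(ann(f"c{i}", s, s + d))
            if rng.random() < 0.8:
                js, je = int(rng.integers(-4, 5)), int(rng.integers(-4, 5))
                a, b = max(0, s + js), max(0, s + js + 1, s + d + je)
                dets.append(det(f"c{i}", a, b))
        f1s = [f for _, f in froc_curve(dets, anns, DEFAULT_FROC_GRID)]
        assert all(x >= y - 1e-12 for x, y in zip(f1s, f1s[1:]))

    def test_unsorted_grid_rejected(self):
        with pytest.raises(ValueError):
            froc_curve([], [], [0.5, 0.2])


class TestGroupedKFold:
    @staticmethod
    def _annotations(n_participants, events_per=2, seed=0):
        rng = np.random.default_rng(seed)
        anns = []
        for p in range(n_participants):
            for e in range(events_per + int(rng.integers(0, 3))):
                s = int(rng.integers(22, 40))
                anns.append(ann(f"c{p}_{e}", s, s + 3, pid=f"p{p:02d}"))
        return anns

    def test_27_participants_5_folds_sizes_5_to_6(self):
        anns = self._annotations(27)
        folds = grouped_kfold(anns, k=5, seed=0)
        sizes = [len(test) for _, test in folds]
        assert sorted(sizes) == [5, 5, 5, 6, 6]

    def test_partition_covers_all_events_disjointly(self):
        anns = self._annotations(12)
        folds = grouped_kfold(anns, k=4, seed=1)
        all_test = [p for _, test in folds for p in test]
        assert sorted(all_test) == sorted({a.participant_id for a in anns})

    def test_no_participant_leakage(self):
        anns = self._annotations(10)
        for train, test in grouped_kfold(anns, k=5, seed=3):
            assert not set(train) & set(test)
            assert sorted(train + test) == sorted(
                {a.participant_id for a in anns}
            )

    def test_determinism(self):
        anns = self._annotations(15)
        assert grouped_kfold(anns, 5, seed=7) == grouped_kfold(anns, 5, seed=7)
        assert grouped_kfold(anns, 5, seed=7) != grouped_kfold(anns, 5, seed=8)

    def test_k_exceeding_participants_rejected(self):
        anns = self._annotations(3)
        with pytest.raises(ValueError):
            grouped_kfold(anns, k=4)
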