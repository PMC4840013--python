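"""Event matching: overlap semantics, metrics, and the brute-force oracle."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sdaeval import (
    DetectionEvent,
    RecordMeta,
    SeizureAnnotation,
    epoch_metrics,
    fd_rate,
    match_events,
    seizure_detection_rate,
    threshold_sweep,
)


def ann(start, end, record="r1"):
    return SeizureAnnotation(record_id=record, start=start, end=end)


def det(start, duration, record="r1", threshold=0.5):
    return DetectionEvent(record_id=record, threshold=threshold, start=start, duration=duration)


def oracle_match(gold, detections):
    """Independent quadratic overlap oracle on half-open intervals."""
    flags = [
        any(g.start < d.start + d.duration and d.start < g.end for d in detections)
        for g in gold
    ]
    fds = [
        d
        for d in detections
        if not any(g.start < d.start + d.duration and d.start < g.end for g in gold)
    ]
    return flags, fds


class TestMatchEvents:
    def test_overlapping_detection_marks_seizure_detected(self):
        res = match_events([ann(10, 60)], [det(50, 20)])
        assert res.detected_flags == [True]
        assert res.false_detections == []

    def test_no_detections_all_missed(self):
        res = match_events([ann(10, 60), ann(100, 130)], [])
        assert res.detected_flags == [False, False]
        assert seizure_detection_rate(res.detected_flags) == 0.0

    def test_multiple_detections_one_seizure_counted_once(self):
        gold = [ann(100, 400)]
        dets = [det(110, 20), det(200, 50), det(390, 30), det(900, 10)]
        res = match_events(gold, dets)
        assert res.detected_flags == [True]
        assert len(res.false_detections) == 1
        assert res.false_detections[0].start == 900

    def test_adjacent_halfopen_intervals_do_not_overlap(self):
        # detection [60, 70) starts exactly where the seizure [10, 60) ends
        res = match_events([ann(10, 60)], [det(60, 10)])
        assert res.detected_flags == [False]
        assert len(res.false_detections) == 1

    def test_tolerance_rescues_near_miss(self):
        res = match_events([ann(10, 60)], [det(62, 10)], tolerance=5.0)
        assert res.detected_flags == [True]

    def test_event_spanning_two_seizures_detects_both_not_fd(self):
        res = match_events([ann(10, 30), ann(40, 60)], [det(25, 20)])
        assert res.detected_flags == [True, True]
        assert res.false_detections == []

    def test_mixed_record_ids_rejected(self):
        with pytest.raises(ValueError, match="mixed record"):
            match_events([ann(0, 10, record="r1")], [det(0, 5, record="r2")])

    @settings(max_examples=200, deadline=None)
    @given(st.data())
    def test_partition_matches_bruteforce_oracle(self, data):
        """Every detector event is matched or a false detection, never both,
        and flags equal the quadratic oracle's."""
        n_gold = data.draw(st.integers(0, 8))
        n_det = data.draw(st.integers(0, 8))
        gold = []
        for _ in range(n_gold):
            s = data.draw(st.integers(0, 500))
            d = data.draw(st.integers(1, 100))
            gold.append(ann(float(s), float(s + d)))
        dets = []
        for _ in range(n_det):
            s = data.draw(st.integers(0, 500))
            d = data.draw(st.integers(1, 100))
            dets.append(det(float(s), float(d)))
        res = match_events(gold, dets)
        flags, fds = oracle_match(gold, dets)
        assert res.detected_flags == flags
        assert res.false_detections == fds
        matched = [d for d in dets if d not in res.false_detections]
        assert len(matched) + len(res.false_detections) == len(dets)


class TestRates:
    def test_detection_rate_extremes(self):
        assert seizure_detection_rate([False] * 4) == 0.0
        assert seizure_detection_rate([True] * 4) == 100.0

    def test_detection_rate_exact_arithmetic(self):
        flags = [True] * 419 + [False] * 2
        assert seizure_detection_rate(flags) == pytest.approx(100 * 419 / 421)
        assert seizure_detection_rate(flags) == pytest.approx(99.525, abs=5e-4)

    def test_detection_rate_undefined_for_no_seizures(self):
        with pytest.raises(ZeroDivisionError):
            seizure_detection_rate([])

    def test_fd_rate(self):
        assert fd_rate([det(0, 5), det(10, 5), det(20, 5)], 1.5) == 2.0
        assert fd_rate([], 10.0) == 0.0
        assert fd_rate(7, 2.0) == 3.5
        with pytest.raises(ValueError):
            fd_rate([], 0.0)

    def test_fd_rate_recovers_planted_poisson_rate(self, rng):
        """100 h with lambda = 1/hr: estimate within 3 SE of 1.0."""
        hours = 100.0
        n = rng.poisson(1.0 * hours)
        events = [det(float(i * 10), 5.0) for i in range(n)]
        rate = fd_rate(events, hours)
        se = np.sqrt(1.0 / hours)
        assert abs(rate - 1.0) <= 3 * se


class TestEpochMetrics:
    record = RecordMeta(record_id="r1", baby_id="b1", duration_hours=10 / 3600)

    def test_perfect_agreement(self):
        gold = [ann(2, 4)]
        dets = [det(2, 2)]
        sens, spec = epoch_metrics(gold, dets, self.record, epoch_len=1.0)
        assert sens == 100.0 and spec == 100.0

    def test_no_detections(self):
        sens, spec = epoch_metrics([ann(2, 4)], [], self.record, epoch_len=1.0)
        assert sens == 0.0 and spec == 100.0

    def test_hand_tallied_confusion_counts(self):
        # 10 epochs of 1 s; gold covers epochs {2,3}; detector {3,4,5}
        # TP=1, FN=1, FP=2, TN=6 -> sens 50%, spec 75%
        sens, spec = epoch_metrics([ann(2, 4)], [det(3, 3)], self.record, epoch_len=1.0)
        assert sens == pytest.approx(50.0)
        assert spec == pytest.approx(75.0)

    def test_record_shorter_than_epoch_rejected(self):
        with pytest.raises(ValueError, match="shorter"):
            epoch_metrics([], [], self.record, epoch_len=60.0)


class TestThresholdSweep:
    records = [
        RecordMeta(record_id="r1", baby_id="b1", duration_hours=2.0),
        RecordMeta(record_id="r2", baby_id="b2", duration_hours=1.0),
    ]
    gold = {"r1": [ann(100, 200), ann(3000, 3100)], "r2": [ann(50, 120, record="r2")]}

    def test_nested_sets_give_monotone_counts(self):
        base = [
            det(150, 30, threshold=0.4),
            det(500, 20, threshold=0.4),
            det(60, 30, record="r2", threshold=0.4),
            det(2000, 15, record="r2", threshold=0.4),
        ]
        mid = [
            DetectionEvent(d.record_id, 0.5, d.start, d.duration)
            for d in base[:3]
        ]
        top = [DetectionEvent(d.record_id, 0.6, d.start, d.duration) for d in base[:1]]
        sweep = threshold_sweep(self.gold, {0.4: base, 0.5: mid, 0.6: top}, self.records)
        detected = [sweep[t].n_detected for t in (0.4, 0.5, 0.6)]
        fds = [len(sweep[t].false_detections) for t in (0.4, 0.5, 0.6)]
        assert detected == sorted(detected, reverse=True)
        assert fds == sorted(fds, reverse=True)

    def test_single_threshold_sweep(self):
        sweep = threshold_sweep(self.gold, {0.5: []}, self.records)
        assert list(sweep) == [0.5]
        assert sweep[0.5].seizure_detection_rate == 0.0

    def test_pooled_fd_rate_weighted_by_duration(self):
        dets = [det(500, 20, threshold=0.4), det(2000, 15, record="r2", threshold=0.4)]
        sweep = threshold_sweep(self.gold, {0.4: dets}, self.records)
        assert sweep[0.4].fd_per_hour == pytest.approx(2 / 3.0)

    def test_pooled_matches_independent_per_record_runs(self):
        dets = [
            det(150, 30, threshold=0.4),
            det(500, 20, threshold=0.4),
            det(60, 30, record="r2", threshold=0.4),
        ]
        sweep = threshold_sweep(self.gold, {0.4: dets}, self.records)
        r1 = match_events(self.gold["r1"], [d for d in dets if d.record_id == "r1"])
        r2 = match_events(self.gold["r2"], [d for d in dets if d.record_id == "r2"])
        assert sweep[0.4].n_detected == r1.n_detected + r2.n_detected
        assert len(sweep[0.4].false_detections) == len(r1.false_detections) + len(
            r2.false_detections
        )

    def test_missing_threshold_list_rejected(self):
        with pytest.raises(ValueError):
            threshold_sweep(self.gold, {}, self.records)
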