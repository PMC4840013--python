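"""Event matching of detector output against gold-standard annotations.

A gold seizure counts as *detected* if at least one detector event overlaps
it anywhere within its time span, on any channel and for any overlap
duration (the spatio-temporal manifold rule). A detector event that overlaps
no gold seizure is a *false detection*. Every detector event is therefore
classified exactly once: matched or false, never both.

Intervals are half-open ``[start, end)``; overlap means
``a.start < b.end and b.start < a.end``. A symmetric temporal tolerance
(default 0 s) may be applied to detector events before matching.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .records import DetectionEvent, RecordMeta, SeizureAnnotation

__all__ = [
    "MatchResult",
    "match_events",
    "seizure_detection_rate",
    "fd_rate",
    "epoch_metrics",
    "threshold_sweep",
]


@dataclass
class MatchResult:
    """Matching outcome for one threshold (one record or pooled)."""

    threshold: float
    detected_flags: list[bool]
    false_detections: list[DetectionEvent]
    seizure_detection_rate: float | None = None   # percent, None if no gold
    fd_per_hour: float | None = None
    epoch_sensitivity: float | None = None        # percent
    epoch_specificity: float | None = None        # percent

    @property
    def n_detected(self) -> int:
        return int(sum(self.detected_flags))

    @property
    def n_gold(self) -> int:
        return len(self.detected_flags)


def _overlaps(a_start: float, a_end: float, b_start: float, b_end: float) -> bool:
    return a_start < b_end and b_start < a_end


def match_events(
    gold: Sequence[SeizureAnnotation],
    detections: Sequence[DetectionEvent],
    tolerance: float = 0.0,
) -> MatchResult:
    """Match detector events against gold seizures of a single record and
    threshold.

    Parameters
    ----------
    gold, detections
        Annotation and event lists; all items must share one record id, and
        all detections one threshold.
    tolerance : float
        Symmetric slack in seconds added to each detector event before
        testing overlap. Default 0 (any nonzero overlap counts).

    Returns
    -------
    MatchResult
        ``detected_flags`` aligned with ``gold``; ``false_detections`` holds
        the events overlapping no gold seizure. An event overlapping two
        gold seizures marks both detected and is not a false detection.
    """
    if tolerance < 0:
        raise ValueError("tolerance must be >= 0")
    record_ids = {g.record_id for g in gold} | {d.record_id for d in detections}
    if len(record_ids) > 1:
        raise ValueError(f"mixed record ids in one match: {sorted(record_ids)}")
    thresholds = {d.threshold for d in detections}
    if len(thresholds) > 1:
        raise ValueError(f"mixed thresholds in one match: {sorted(thresholds)}")
    threshold = thresholds.pop() if thresholds else float("nan")

    flags = [False] * len(gold)
    false_detections: list[DetectionEvent] = []
    for det in detections:
        d_start, d_end = det.start - tolerance, det.end + tolerance
        hit = False
        for i, g in enumerate(gold):
            if _overlaps(d_start, d_end, g.start, g.end):
                flags[i] = True
                hit = True
        if not hit:
            false_detections.append(det)
    return MatchResult(
        threshold=threshold, detected_flags=flags, false_detections=false_detections
    )


def seizure_detection_rate(flags: Sequence[bool]) -> float:
    """Percentage of gold seizures detected: ``100 * detected / total``.

    Undefined (raises) when there are no gold seizures.
    """
    if len(flags) == 0:
        raise ZeroDivisionError(
            "seizure detection rate is undefined with zero gold seizures"
        )
    return 100.0 * sum(bool(f) for f in flags) / len(flags)


def fd_rate(false_detections: Sequence[DetectionEvent] | int, total_hours: float) -> float:
    """False detections per hour over ``total_hours`` of recording.

    ``false_detections`` may be the event list or a bare count.
    """
    if not total_hours > 0:
        raise ValueError(f"total_hours must be > 0, got {total_hours}")
    count = false_detections if isinstance(false_detections, int) else len(false_detections)
    return count / total_hours


def epoch_metrics(
    gold: Sequence[SeizureAnnotation],
    detections: Sequence[DetectionEvent],
    record: RecordMeta,
    epoch_len: float = 1.0,
) -> tuple[float, float]:
    """Epoch-based sensitivity and specificity, in percent.

    The record is tiled into non-overlapping epochs of ``epoch_len``
    seconds. An epoch is gold-positive (resp. detector-positive) if it
    overlaps any gold (resp. detector) interval. Sensitivity is
    ``TP/(TP+FN)``; specificity ``TN/(TN+FP)``; either is ``nan`` when its
    denominator is zero (e.g. a record with no seizure time).
    """
    if not epoch_len > 0:
        raise ValueError("epoch_len must be > 0")
    total = record.duration_seconds
    n_epochs = int(total // epoch_len)
    if n_epochs < 1:
        raise ValueError(
            f"record {record.record_id!r} ({total} s) is shorter than one "
            f"epoch ({epoch_len} s)"
        )
    edges = np.arange(n_epochs + 1) * epoch_len
    gold_pos = np.zeros(n_epochs, dtype=bool)
    det_pos = np.zeros(n_epochs, dtype=bool)
    for intervals, out in ((gold, gold_pos), (detections, det_pos)):
        for iv in intervals:
            end = iv.end if hasattr(iv, "end") else iv.start + iv.duration
            lo = int(np.searchsorted(edges, iv.start, side="right")) - 1
            hi = int(np.searchsorted(edges, end, side="left"))
            out[max(lo, 0) : min(hi, n_epochs)] = True
    tp = int(np.sum(gold_pos & det_pos))
    fn = int(np.sum(gold_pos & ~det_pos))
    fp = int(np.sum(~gold_pos & det_pos))
    tn = int(np.sum(~gold_pos & ~det_pos))
    sens = 100.0 * tp / (tp + fn) if tp + fn else float("nan")
    spec = 100.0 * tn / (tn + fp) if tn + fp else float("nan")
    return sens, spec


def threshold_sweep(
    gold_by_record: Mapping[str, Sequence[SeizureAnnotation]],
    detections_by_threshold: Mapping[float, Sequence[DetectionEvent]],
    records: Sequence[RecordMeta],
    tolerance: float = 0.0,
    epoch_len: float | None = None,
) -> dict[float, MatchResult]:
    """Run matching at every threshold, pooling across records.

    Pooled seizure detection rate counts all gold seizures over all records;
    the false-detection rate divides the pooled FD count by the summed
    record duration (so longer records weigh more). Requires at least one
    detection list (possibly empty) per threshold.

    Returns a dict threshold -> pooled :class:`MatchResult`, with
    per-record results attached as ``result.per_record``.
    """
    if not detections_by_threshold:
        raise ValueError("no detection lists supplied")
    record_meta = {r.record_id: r for r in records}
    unknown = set(gold_by_record) - set(record_meta)
    if unknown:
        raise ValueError(f"annotations reference unknown records: {sorted(unknown)}")
    total_hours = sum(r.duration_hours for r in records)

    sweep: dict[float, MatchResult] = {}
    for threshold in sorted(detections_by_threshold):
        events = detections_by_threshold[threshold]
        by_record: dict[str, list[DetectionEvent]] = {rid: [] for rid in record_meta}
        for ev in events:
            if ev.record_id not in record_meta:
                raise ValueError(f"event references unknown record {ev.record_id!r}")
            by_record[ev.record_id].append(ev)

        flags: list[bool] = []
        fds: list[DetectionEvent] = []
        per_record: dict[str, MatchResult] = {}
        for rid, meta in record_meta.items():
            gold = list(gold_by_record.get(rid, ()))
            res = match_events(gold, by_record[rid], tolerance=tolerance)
            res.threshold = threshold
            if gold:
                res.seizure_detection_rate = seizure_detection_rate(res.detected_flags)
            res.fd_per_hour = fd_rate(res.false_detections, meta.duration_hours)
            if epoch_len is not None:
                sens, spec = epoch_metrics(gold, by_record[rid], meta, epoch_len)
                res.epoch_sensitivity, res.epoch_specificity = sens, spec
            per_record[rid] = res
            flags.extend(res.detected_flags)
            fds.extend(res.false_detections)

        pooled = MatchResult(
            threshold=threshold,
            detected_flags=flags,
            false_detections=fds,
            seizure_detection_rate=seizure_detection_rate(flags) if flags else None,
            fd_per_hour=fd_rate(fds, total_hours),
        )
        pooled.per_record = per_record  # type: ignore[attr-defined]
        sweep[threshold] = pooled
    return sweep
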