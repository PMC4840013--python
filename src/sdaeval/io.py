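"""Readers and writers for annotation lists, detector event lists, feature
tables and report tables.

All text I/O is delimited (comma by default), UTF-8, with a header row.
Column names are configurable through a :class:`TableSchema`, since exported
annotation lists differ between EEG vendors. Input times may be clock times;
:func:`clock_to_seconds` converts them given the record start time.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .records import (
    DetectionEvent,
    FalseDetectionRecord,
    RecordMeta,
    SeizureAnnotation,
)

logger = logging.getLogger(__name__)

__all__ = [
    "TableSchema",
    "clock_to_seconds",
    "read_records",
    "read_annotations",
    "read_detections",
    "write_annotations",
    "write_detections",
    "write_report_tables",
    "read_feature_table",
    "read_fd_labels",
    "write_fd_labels",
    "read_eeg_csv",
    "write_eeg_csv",
    "read_eeg_edf",
]


@dataclass
class TableSchema:
    """Column-name mapping and dialect for delimited annotation exports."""

    record_col: str = "record_id"
    start_col: str = "start"
    end_col: str = "end"
    duration_col: str = "duration"
    channel_col: str = "peak_channel"
    annotator_col: str = "annotator"
    delimiter: str = ","


def clock_to_seconds(clock: str | pd.Timestamp, record_start: str | pd.Timestamp) -> float:
    """Convert a clock time to seconds from record start.

    Times past midnight relative to the start are rolled into the next day
    when the naive difference would be negative (overnight recordings).
    """
    t = pd.Timestamp(clock)
    t0 = pd.Timestamp(record_start)
    delta = (t - t0).total_seconds()
    if delta < 0:
        delta += 86400.0
    return delta


def _read_delimited(path: str | Path, delimiter: str) -> pd.DataFrame:
    path = Path(path)
    try:
        frame = pd.read_csv(path, sep=delimiter)
    except pd.errors.EmptyDataError as exc:
        raise ValueError(f"{path}: file is empty (expected a header row)") from exc
    return frame


def _require_columns(frame: pd.DataFrame, cols: Iterable[str], path: Path) -> None:
    missing = [c for c in cols if c not in frame.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}; found {list(frame.columns)}")


def read_records(path: str | Path, schema: TableSchema | None = None) -> list[RecordMeta]:
    """Read record metadata (record id, baby id, duration in hours, group)."""
    schema = schema or TableSchema()
    path = Path(path)
    frame = _read_delimited(path, schema.delimiter)
    _require_columns(frame, [schema.record_col, "baby_id", "duration_hours"], path)
    records = []
    for i, row in frame.iterrows():
        try:
            records.append(
                RecordMeta(
                    record_id=str(row[schema.record_col]),
                    baby_id=str(row["baby_id"]),
                    duration_hours=float(row["duration_hours"]),
                    group=str(row.get("group", "seizure")),
                )
            )
        except (ValueError, TypeError) as exc:
            raise ValueError(f"{path} line {i + 2}: {exc}") from exc
    return records


def read_annotations(
    path: str | Path,
    schema: TableSchema | None = None,
    record_durations: Mapping[str, float] | None = None,
) -> list[SeizureAnnotation]:
    """Read gold-standard seizure annotations, validated and sorted by
    (record_id, start).

    Parameters
    ----------
    path : path
        Delimited text with a header; columns for record, start and end
        (seconds from record start).
    schema : TableSchema, optional
        Column-name mapping.
    record_durations : mapping, optional
        record_id -> duration in *hours*; when given, annotations must lie
        within the record.
    """
    schema = schema or TableSchema()
    path = Path(path)
    frame = _read_delimited(path, schema.delimiter)
    _require_columns(frame, [schema.record_col, schema.start_col, schema.end_col], path)
    annotations = []
    for i, row in frame.iterrows():
        try:
            ann = SeizureAnnotation(
                record_id=str(row[schema.record_col]),
                start=float(row[schema.start_col]),
                end=float(row[schema.end_col]),
                annotator=str(row[schema.annotator_col])
                if schema.annotator_col in frame.columns
                else "",
            )
        except (ValueError, TypeError) as exc:
            raise ValueError(f"{path} line {i + 2}: {exc}") from exc
        _check_within_record(ann.record_id, ann.end, record_durations, path, i)
        annotations.append(ann)
    annotations.sort(key=lambda a: (a.record_id, a.start))
    logger.info("read %d annotations from %s", len(annotations), path)
    return annotations


def read_detections(
    path: str | Path,
    threshold: float,
    schema: TableSchema | None = None,
    record_durations: Mapping[str, float] | None = None,
) -> list[DetectionEvent]:
    """Read a detector event list (onset, duration, peak channel) exported
    at one sensitivity threshold; events are tagged with that threshold."""
    if not 0.0 <= threshold <= 1.0:
        raise ValueError(f"threshold must be in [0, 1], got {threshold}")
    schema = schema or TableSchema()
    path = Path(path)
    frame = _read_delimited(path, schema.delimiter)
    _require_columns(frame, [schema.record_col, schema.start_col, schema.duration_col], path)
    events = []
    for i, row in frame.iterrows():
        channel = row[schema.channel_col] if schema.channel_col in frame.columns else ""
        channel = "" if pd.isna(channel) else str(channel)
        try:
            ev = DetectionEvent(
                record_id=str(row[schema.record_col]),
                threshold=threshold,
                start=float(row[schema.start_col]),
                duration=float(row[schema.duration_col]),
                peak_channel=channel,
            )
        except (ValueError, TypeError) as exc:
            raise ValueError(f"{path} line {i + 2}: {exc}") from exc
        _check_within_record(ev.record_id, ev.end, record_durations, path, i)
        events.append(ev)
    events.sort(key=lambda e: (e.record_id, e.start))
    logger.info("read %d events at threshold %.2f from %s", len(events), threshold, path)
    return events


def _check_within_record(
    record_id: str,
    end_seconds: float,
    record_durations: Mapping[str, float] | None,
    path: Path,
    row_index: int,
) -> None:
    if record_durations is None:
        return
    if record_id not in record_durations:
        raise ValueError(f"{path} line {row_index + 2}: unknown record {record_id!r}")
    limit = record_durations[record_id] * 3600.0
    if end_seconds > limit + 1e-9:
        raise ValueError(
            f"{path} line {row_index + 2}: interval ends at {end_seconds} s, "
            f"beyond record {record_id!r} duration {limit} s"
        )


def write_annotations(
    annotations: Iterable[SeizureAnnotation],
    path: str | Path,
    schema: TableSchema | None = None,
) -> None:
    schema = schema or TableSchema()
    frame = pd.DataFrame(
        [
            {
                schema.record_col: a.record_id,
                schema.start_col: a.start,
                schema.end_col: a.end,
                schema.annotator_col: a.annotator,
            }
            for a in annotations
        ],
        columns=[schema.record_col, schema.start_col, schema.end_col, schema.annotator_col],
    )
    frame.to_csv(path, sep=schema.delimiter, index=False)


def write_detections(
    events: Iterable[DetectionEvent],
    path: str | Path,
    schema: TableSchema | None = None,
) -> None:
    schema = schema or TableSchema()
    frame = pd.DataFrame(
        [
            {
                schema.record_col: e.record_id,
                "threshold": e.threshold,
                schema.start_col: e.start,
                schema.duration_col: e.duration,
                schema.channel_col: e.peak_channel,
            }
            for e in events
        ],
        columns=[
            schema.record_col,
            "threshold",
            schema.start_col,
            schema.duration_col,
            schema.channel_col,
        ],
    )
    frame.to_csv(path, sep=schema.delimiter, index=False)


def read_feature_table(path: str | Path, delimiter: str = ",") -> pd.DataFrame:
    """Read a per-seizure feature table (one row per seizure)."""
    return _read_delimited(path, delimiter)


def write_report_tables(
    results: Mapping[str, pd.DataFrame],
    outdir: str | Path,
    delimiter: str = ",",
) -> dict[str, Path]:
    """Write analysis outputs as delimited report tables.

    ``results`` maps a table name (e.g. ``"per_threshold_metrics"``,
    ``"odds_ratios"``, ``"fd_categories"``) to a DataFrame. Returns the
    written paths. An empty mapping is an error: a report needs at least one
    completed analysis component.
    """
    if not results:
        raise ValueError("no analysis components to write")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    for name, frame in results.items():
        if frame is None:
            raise ValueError(f"analysis component {name!r} is missing")
        path = outdir / f"{name}.csv"
        frame.to_csv(path, sep=delimiter, index=False)
        written[name] = path
        logger.info("wrote %s (%d rows)", path, len(frame))
    return written


def read_fd_labels(path: str | Path, delimiter: str = ",") -> list[FalseDetectionRecord]:
    """Read expert false-detection labels: columns ``record_id``,
    ``threshold``, ``start``, ``duration``, ``category`` and (for
    no-artefact rows) ``subcategory``."""
    path = Path(path)
    frame = _read_delimited(path, delimiter)
    _require_columns(frame, ["record_id", "threshold", "start", "duration", "category"], path)
    records = []
    for i, row in frame.iterrows():
        sub = row.get("subcategory")
        if pd.isna(sub) or sub == "":
            sub = None
        channel = row.get("peak_channel", "")
        channel = "" if pd.isna(channel) else str(channel)
        try:
            records.append(
                FalseDetectionRecord(
                    DetectionEvent(
                        record_id=str(row["record_id"]),
                        threshold=float(row["threshold"]),
                        start=float(row["start"]),
                        duration=float(row["duration"]),
                        peak_channel=channel,
                    ),
                    category=str(row["category"]),
                    background_subcategory=sub,
                )
            )
        except (ValueError, TypeError) as exc:
            raise ValueError(f"{path} line {i + 2}: {exc}") from exc
    return records


def write_fd_labels(
    records: Iterable[FalseDetectionRecord], path: str | Path, delimiter: str = ","
) -> None:
    frame = pd.DataFrame(
        [
            {
                "record_id": r.event.record_id,
                "threshold": r.event.threshold,
                "start": r.event.start,
                "duration": r.event.duration,
                "peak_channel": r.event.peak_channel,
                "category": r.category,
                "subcategory": r.background_subcategory or "",
            }
            for r in records
        ],
        columns=[
            "record_id", "threshold", "start", "duration",
            "peak_channel", "category", "subcategory",
        ],
    )
    frame.to_csv(path, sep=delimiter, index=False)


# --- EEG segment exchange -------------------------------------------------

def write_eeg_csv(
    samples: np.ndarray,
    channels: Iterable[str],
    sfreq: float,
    path: str | Path,
) -> None:
    """Write a multichannel EEG segment as CSV: a ``time`` column in seconds
    plus one column per channel, amplitudes in microvolts."""
    samples = np.atleast_2d(np.asarray(samples, dtype=float))
    channels = list(channels)
    if samples.shape[0] != len(channels):
        raise ValueError(f"{samples.shape[0]} rows for {len(channels)} channels")
    t = np.arange(samples.shape[1]) / sfreq
    frame = pd.DataFrame({"time": t})
    for label, row in zip(channels, samples):
        frame[label] = row
    frame.to_csv(path, index=False)


def read_eeg_csv(path: str | Path) -> tuple[np.ndarray, list[str], float]:
    """Read an EEG CSV written by :func:`write_eeg_csv`.

    Returns ``(samples, channels, sfreq)`` with samples shaped
    (n_channels, n_samples).
    """
    frame = pd.read_csv(path)
    if "time" not in frame.columns or len(frame) < 2:
        raise ValueError(f"{path}: expected a 'time' column and >= 2 samples")
    t = frame["time"].to_numpy(dtype=float)
    sfreq = 1.0 / float(np.median(np.diff(t)))
    channels = [c for c in frame.columns if c != "time"]
    samples = frame[channels].to_numpy(dtype=float).T
    return samples, channels, sfreq


def read_eeg_edf(path: str | Path) -> tuple[np.ndarray, list[str], float]:
    """Read an EDF recording (bipolar montage labels such as ``F4-C4``).

    Requires the optional :mod:`mne` dependency. Returns amplitudes in
    microvolts, shaped (n_channels, n_samples).
    """
    try:
        import mne
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise ImportError("reading EDF requires the optional 'mne' package") from exc
    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    return raw.get_data() * 1e6, list(raw.ch_names), float(raw.info["sfreq"])
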