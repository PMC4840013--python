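"""Worked-example dataset: false-detection counts from a published
two-centre clinical audit of a neonatal SDA.

The audit reviewed 20 term neonates (10 with seizures, 10 seizure-free;
1262.9 h of EEG, 421 expert-annotated seizures of which 419 were confirmed
by a second reader) and categorized every false detection at the three
sensitivity thresholds 0.4, 0.5 and 0.6. Only the published aggregate
counts are bundled here — the underlying EEG is not distributed. The
expander functions turn these counts into record lists so the aggregation
operations can reproduce the published shares by explicit computation.
"""

from __future__ import annotations

from .records import DetectionEvent, FalseDetectionRecord

__all__ = [
    "TOTAL_EEG_HOURS",
    "N_RECORDS",
    "N_SEIZURES_ANNOTATED",
    "N_SEIZURES_CONFIRMED",
    "FD_CATEGORY_COUNTS",
    "NO_ARTEFACT_BREAKDOWN",
    "CONCENTRATION_EXAMPLES",
    "expand_fd_counts",
    "expand_concentration_example",
]

TOTAL_EEG_HOURS = 1262.9
N_RECORDS = 20
N_SEIZURES_ANNOTATED = 421
N_SEIZURES_CONFIRMED = 419

#: False-detection counts per category at each sensitivity threshold.
#: Chewing/sucking and electronic-equipment artefacts had no column of
#: their own in the published table (zero counts).
FD_CATEGORY_COUNTS: dict[float, dict[str, int]] = {
    0.4: {
        "respiration": 278,
        "ecg_pulse": 34,
        "bad_electrode": 21,
        "movement_handling": 57,
        "sweat": 160,
        "unclassified_artefact": 29,
        "no_artefact": 221,
    },
    0.5: {
        "respiration": 249,
        "ecg_pulse": 42,
        "bad_electrode": 11,
        "movement_handling": 16,
        "sweat": 97,
        "unclassified_artefact": 19,
        "no_artefact": 96,
    },
    0.6: {
        "respiration": 221,
        "ecg_pulse": 43,
        "bad_electrode": 4,
        "movement_handling": 4,
        "sweat": 14,
        "unclassified_artefact": 10,
        "no_artefact": 46,
    },
}

#: Background description of the no-artefact false detections.
NO_ARTEFACT_BREAKDOWN: dict[float, dict[str, int]] = {
    0.4: {"highly_rhythmic": 132, "normal_background": 67, "sharp_waves": 20, "low_amplitude": 2},
    0.5: {"highly_rhythmic": 55, "normal_background": 25, "sharp_waves": 15, "low_amplitude": 1},
    0.6: {"highly_rhythmic": 30, "normal_background": 11, "sharp_waves": 5},
}

#: Per-patient concentration examples at threshold 0.4: category ->
#: (top patient id, top patient count, category total). The audit text
#: gives 149 sweat false detections in its concentration example.
CONCENTRATION_EXAMPLES: dict[str, tuple[str, int, int]] = {
    "respiration": ("patient-02", 232, 278),
    "sweat": ("patient-15", 104, 149),
}


def _event(record_id: str, threshold: float, index: int) -> DetectionEvent:
    # placeholder timing: the audit publishes counts, not event times
    return DetectionEvent(
        record_id=record_id, threshold=threshold, start=10.0 * index, duration=10.0
    )


def expand_fd_counts(threshold: float) -> list[FalseDetectionRecord]:
    """Expand the published per-category counts at ``threshold`` into one
    :class:`FalseDetectionRecord` per false detection."""
    if threshold not in FD_CATEGORY_COUNTS:
        raise KeyError(
            f"no audit counts at threshold {threshold}; "
            f"available: {sorted(FD_CATEGORY_COUNTS)}"
        )
    counts = FD_CATEGORY_COUNTS[threshold]
    breakdown = NO_ARTEFACT_BREAKDOWN[threshold]
    if sum(breakdown.values()) != counts["no_artefact"]:
        raise AssertionError("no-artefact breakdown inconsistent with category count")
    records: list[FalseDetectionRecord] = []
    i = 0
    for category, n in counts.items():
        if category == "no_artefact":
            for sub, m in breakdown.items():
                for _ in range(m):
                    records.append(
                        FalseDetectionRecord(
                            _event("audit-record", threshold, i),
                            "no_artefact",
                            background_subcategory=sub,
                        )
                    )
                    i += 1
        else:
            for _ in range(n):
                records.append(
                    FalseDetectionRecord(_event("audit-record", threshold, i), category)
                )
                i += 1
    return records


def expand_concentration_example(category: str) -> list[FalseDetectionRecord]:
    """Expand a published per-patient concentration example (threshold 0.4)
    into records: the dominant patient's count plus the remainder spread one
    per synthetic other patient."""
    if category not in CONCENTRATION_EXAMPLES:
        raise KeyError(
            f"no concentration example for {category!r}; "
            f"available: {sorted(CONCENTRATION_EXAMPLES)}"
        )
    top_patient, top_count, total = CONCENTRATION_EXAMPLES[category]
    records = []
    i = 0
    for _ in range(top_count):
        records.append(FalseDetectionRecord(_event(top_patient, 0.4, i), category))
        i += 1
    for k in range(total - top_count):
        records.append(
            FalseDetectionRecord(_event(f"other-{k:03d}", 0.4, i), category)
        )
        i += 1
    return records
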