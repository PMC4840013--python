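"""Core data model for SDA performance analysis.

Times are seconds from record start (float); intervals are half-open
``[start, end)`` so adjacency and overlap are unambiguous. Record durations
are hours. Detector sensitivity thresholds live on a configured grid in
(0, 1); the conventional clinical grid is (0.4, 0.5, 0.6).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "DEFAULT_THRESHOLDS",
    "FD_CATEGORIES",
    "NO_ARTEFACT_SUBCATEGORIES",
    "MORPHOLOGY_CATEGORIES",
    "RecordMeta",
    "SeizureAnnotation",
    "DetectionEvent",
    "ProbabilityTrace",
    "FalseDetectionRecord",
]

#: Clinically relevant sensitivity thresholds of the detector output.
DEFAULT_THRESHOLDS: tuple[float, ...] = (0.4, 0.5, 0.6)

#: Closed vocabulary of false-detection artefact categories.
FD_CATEGORIES: tuple[str, ...] = (
    "respiration",
    "ecg_pulse",
    "chewing_sucking",
    "bad_electrode",
    "movement_handling",
    "electronic_equipment",
    "sweat",
    "unclassified_artefact",
    "no_artefact",
)

#: EEG background description where a false detection had no visible artefact.
NO_ARTEFACT_SUBCATEGORIES: tuple[str, ...] = (
    "normal_background",
    "highly_rhythmic",
    "sharp_waves",
    "low_amplitude",
)

#: Seizure discharge morphology categories. "S/SH" (spikes or sharp waves)
#: may be scored as a single level; a 4-level variant (no RDA) is accepted
#: by the feature validator via configuration.
MORPHOLOGY_CATEGORIES: tuple[str, ...] = (
    "RDD",        # rhythmic discharges of delta
    "RDT",        # rhythmic discharges of theta
    "RDA",        # rhythmic discharges of alpha
    "S/SH",       # spikes or sharp waves
    "SH+W/SP+W",  # sharp-and-slow-wave or spike-and-wave complexes
)


@dataclass(frozen=True)
class RecordMeta:
    """Metadata for one EEG recording.

    Parameters
    ----------
    record_id : str
        Recording identifier.
    baby_id : str
        Patient identifier (several records may share a baby).
    duration_hours : float
        Total recording duration in hours, > 0.
    group : {"seizure", "non-seizure"}
        Whether the baby had any electrographic seizures.
    """

    record_id: str
    baby_id: str
    duration_hours: float
    group: str = "seizure"

    def __post_init__(self) -> None:
        if not self.baby_id:
            raise ValueError(f"record {self.record_id!r}: baby_id must be non-empty")
        if not self.duration_hours > 0:
            raise ValueError(
                f"record {self.record_id!r}: duration_hours must be > 0, "
                f"got {self.duration_hours}"
            )
        if self.group not in ("seizure", "non-seizure"):
            raise ValueError(
                f"record {self.record_id!r}: group must be 'seizure' or "
                f"'non-seizure', got {self.group!r}"
            )

    @property
    def duration_seconds(self) -> float:
        return self.duration_hours * 3600.0


@dataclass(frozen=True)
class SeizureAnnotation:
    """Gold-standard expert seizure annotation, half-open ``[start, end)`` s."""

    record_id: str
    start: float
    end: float
    annotator: str = ""

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(
                f"annotation on {self.record_id!r}: start must be >= 0, got {self.start}"
            )
        if not self.end > self.start:
            raise ValueError(
                f"annotation on {self.record_id!r}: end ({self.end}) must be "
                f"> start ({self.start})"
            )

    @property
    def duration(self) -> float:
        return self.end - self.start


@dataclass(frozen=True)
class DetectionEvent:
    """One detector event at one sensitivity threshold.

    Detectors export onset time, duration and the channel of peak detection
    for each threshold of the grid.
    """

    record_id: str
    threshold: float
    start: float
    duration: float
    peak_channel: str = ""

    def __post_init__(self) -> None:
        if not 0.0 <= self.threshold <= 1.0:
            raise ValueError(
                f"event on {self.record_id!r}: threshold must be in [0, 1], "
                f"got {self.threshold}"
            )
        if not self.duration > 0:
            raise ValueError(
                f"event on {self.record_id!r} at t={self.start}: duration must "
                f"be > 0, got {self.duration}"
            )
        if self.start < 0:
            raise ValueError(
                f"event on {self.record_id!r}: start must be >= 0, got {self.start}"
            )

    @property
    def end(self) -> float:
        return self.start + self.duration


@dataclass
class ProbabilityTrace:
    """Per-channel seizure probability, one value per epoch step.

    ``values`` has shape (n_channels, n_epochs); every entry lies in [0, 1].
    ``epoch_step`` is the hop between consecutive epoch centres in seconds.
    """

    record_id: str
    epoch_step: float
    values: np.ndarray
    channels: Sequence[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if self.epoch_step <= 0:
            raise ValueError("epoch_step must be > 0")
        if self.values.size and (
            self.values.min() < 0.0 or self.values.max() > 1.0
        ):
            raise ValueError("probability values must lie in [0, 1]")
        if self.channels and len(self.channels) != self.values.shape[0]:
            raise ValueError(
                f"{len(self.channels)} channel labels for "
                f"{self.values.shape[0]} channel rows"
            )

    @property
    def n_epochs(self) -> int:
        return self.values.shape[1]

    def max_over_channels(self) -> np.ndarray:
        """Cross-channel summary trace (per-epoch maximum)."""
        return self.values.max(axis=0)


@dataclass(frozen=True)
class FalseDetectionRecord:
    """A detector event not coincident with any gold seizure, with its
    expert-assigned artefact category.

    ``background_subcategory`` is required exactly when ``category`` is
    ``"no_artefact"`` — it describes the EEG background at the time of the
    false detection.
    """

    event: DetectionEvent
    category: str
    background_subcategory: str | None = None

    def __post_init__(self) -> None:
        if self.category not in FD_CATEGORIES:
            raise ValueError(
                f"unknown false-detection category {self.category!r}; "
                f"expected one of {FD_CATEGORIES}"
            )
        if self.category == "no_artefact":
            if self.background_subcategory not in NO_ARTEFACT_SUBCATEGORIES:
                raise ValueError(
                    "category 'no_artefact' requires a background_subcategory "
                    f"from {NO_ARTEFACT_SUBCATEGORIES}, "
                    f"got {self.background_subcategory!r}"
                )
        elif self.background_subcategory is not None:
            raise ValueError(
                "background_subcategory is only valid for category 'no_artefact'"
            )
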