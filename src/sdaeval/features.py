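"""The 10-criterion seizure assessment schema and its quantitative helpers.

The schema scores each expert-annotated seizure on signal-signature
features (peak amplitude, rhythmicity, EEG background, morphology at onset
and at peak), temporal-context features (duration, frequency variability,
morphology change from onset to peak) and spatial-context features (number
of channels involved at onset and at peak).

Visual scores (rhythmicity, background, morphology, channel counts) are
manual-entry inputs scored by an electroencephalographer; the automated
estimators here (:func:`peak_amplitude`, :func:`dominant_frequency`) are
helpers for synthetic data and never silently substitute expert scores.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as sps

from .records import MORPHOLOGY_CATEGORIES

__all__ = [
    "FEATURE_COLUMNS",
    "RHYTHMICITY_LEVELS",
    "BACKGROUND_LEVELS",
    "frequency_variability",
    "peak_amplitude",
    "DominantFrequency",
    "dominant_frequency",
    "morphology_change",
    "validate_feature_table",
]

#: Rhythmicity: visual 3-level ordinal of second-to-second regularity.
RHYTHMICITY_LEVELS = {1: "significant dysrhythmia", 2: "minimal dysrhythmia", 3: "highly rhythmic"}
#: EEG background at the time of the seizure, 3-level ordinal.
BACKGROUND_LEVELS = {1: "normal", 2: "moderate abnormality", 3: "severe abnormality"}

#: Canonical feature-table columns, one row per seizure.
FEATURE_COLUMNS = (
    "seizure_id",
    "baby_id",
    "peak_amplitude",          # microvolts, peak to trough
    "rhythmicity",             # 1..3
    "background_score",        # 1..3
    "morphology_onset",        # category
    "morphology_peak",         # category
    "duration",                # seconds
    "frequency_variability",   # Hz (sample SD of start/peak/end frequency)
    "morphology_change",       # bool
    "n_channels_onset",
    "n_channels_peak",
)


def frequency_variability(f_start: float, f_peak: float, f_end: float) -> float:
    """Frequency variability over the span of a seizure, in Hz.

    Sample standard deviation (n−1 denominator) of the discharge frequency
    measured at the start (first 5 s), peak (mid seizure) and end (last 5 s)
    of the seizure.
    """
    freqs = np.array([f_start, f_peak, f_end], dtype=float)
    if np.any(freqs <= 0):
        raise ValueError(f"discharge frequencies must be > 0 Hz, got {freqs.tolist()}")
    return float(np.std(freqs, ddof=1))


def peak_amplitude(
    segment: np.ndarray, sfreq: float, window: float | None = None
) -> float:
    """Peak-to-trough amplitude (µV) of the highest-amplitude discharge,
    measured at the midpoint of the seizure.

    Parameters
    ----------
    segment : array
        Single-channel EEG in microvolts, centred on the seizure midpoint.
    sfreq : float
        Sampling rate in Hz.
    window : float, optional
        Width in seconds of the mid-segment analysis window; the whole
        segment is used when omitted.
    """
    x = np.asarray(segment, dtype=float).ravel()
    if x.size == 0:
        raise ValueError("empty EEG segment")
    if window is not None:
        half = int(round(window * sfreq / 2))
        mid = x.size // 2
        x = x[max(mid - half, 0) : mid + half]
        if x.size == 0:
            raise ValueError("analysis window is empty")
    return float(x.max() - x.min())


@dataclass(frozen=True)
class DominantFrequency:
    """Spectral-peak frequency estimate with a confidence flag.

    ``confident`` is False when the peak does not stand out from the rest of
    the band (prominence ratio below the threshold used by
    :func:`dominant_frequency`), e.g. on broadband noise.
    """

    frequency: float
    confident: bool
    prominence: float


def dominant_frequency(
    segment: np.ndarray,
    sfreq: float,
    band: tuple[float, float] = (0.3, 8.0),
    prominence_threshold: float = 4.0,
) -> DominantFrequency:
    """Dominant discharge frequency of a single-channel segment.

    Estimated as the Welch spectral peak within ``band`` (default 0.3–8 Hz,
    covering the delta/theta/alpha discharge range of neonatal seizures),
    after dividing out the power-law trend of the in-band spectrum so the
    1/f tilt of background EEG does not masquerade as a low-frequency
    discharge. ``prominence`` is the ratio of the detrended peak to the
    detrended median; broadband noise yields a low ratio and the estimate
    is flagged not confident.
    """
    x = np.asarray(segment, dtype=float).ravel()
    if x.size < int(5 * sfreq):
        raise ValueError("segment must be at least 5 s long")
    if np.allclose(x, 0.0):
        raise ValueError("all-zero segment: dominant frequency is undefined")
    nperseg = min(x.size, int(8 * sfreq))
    nfft = max(nperseg, int(32 * sfreq))  # pad for ~0.03 Hz peak resolution
    freqs, psd = sps.welch(x - x.mean(), fs=sfreq, nperseg=nperseg, nfft=nfft)
    in_band = (freqs >= band[0]) & (freqs <= band[1])
    if not np.any(in_band):
        raise ValueError(f"no spectral estimate inside band {band} at sfreq {sfreq}")
    f_band, p_band = freqs[in_band], psd[in_band]
    positive = p_band > 0
    if positive.sum() >= 2:
        slope, icept = np.polyfit(
            np.log10(f_band[positive]), np.log10(p_band[positive]), 1
        )
        trend = 10.0 ** (icept + slope * np.log10(f_band))
    else:
        trend = np.ones_like(f_band)
    resid = np.divide(p_band, trend, out=np.zeros_like(p_band), where=trend > 0)
    k = int(np.argmax(resid))
    med = float(np.median(resid))
    prominence = float(resid[k] / med) if med > 0 else float("inf")
    return DominantFrequency(
        frequency=float(f_band[k]),
        confident=prominence >= prominence_threshold,
        prominence=prominence,
    )


def morphology_change(onset: str, peak: str) -> bool:
    """Whether the discharge morphology differs between seizure onset and
    peak (e.g. rhythmic delta evolving into sharp-and-slow-wave complexes)."""
    for value, which in ((onset, "onset"), (peak, "peak")):
        if value not in MORPHOLOGY_CATEGORIES:
            raise ValueError(
                f"unknown {which} morphology {value!r}; "
                f"expected one of {MORPHOLOGY_CATEGORIES}"
            )
    return onset != peak


def validate_feature_table(
    records: pd.DataFrame,
    n_channels: int = 8,
    morphology_levels: tuple[str, ...] = MORPHOLOGY_CATEGORIES,
) -> tuple[pd.DataFrame, list[str]]:
    """Validate a per-seizure feature table against the schema.

    Issues are collected, not raised: each is a string naming the row
    (by ``seizure_id`` or positional index) and the offending column.
    Returns the table (unchanged) and the issue list; warnings (prefixed
    ``"warning:"``) do not indicate invalid rows.

    ``morphology_levels`` configures the accepted morphology vocabulary
    (the onset scale has five levels; a four-level variant without RDA is
    admissible for peak morphology).
    """
    issues: list[str] = []
    missing = [c for c in FEATURE_COLUMNS if c not in records.columns]
    if missing:
        issues.append(f"table: missing column(s) {missing}")

    for idx, row in records.iterrows():
        label = str(row.get("seizure_id", f"row {idx}"))

        def check(cond: bool, message: str, warning: bool = False) -> None:
            if not cond:
                issues.append(("warning: " if warning else "") + f"{label}: {message}")

        if "peak_amplitude" in records.columns:
            check(row["peak_amplitude"] > 0, "peak_amplitude must be > 0 µV")
        if "duration" in records.columns:
            check(row["duration"] > 0, "duration must be > 0 s")
        if "frequency_variability" in records.columns:
            check(row["frequency_variability"] >= 0, "frequency_variability must be >= 0")
        if "rhythmicity" in records.columns:
            check(row["rhythmicity"] in RHYTHMICITY_LEVELS,
                  f"rhythmicity {row['rhythmicity']!r} not in {sorted(RHYTHMICITY_LEVELS)}")
        if "background_score" in records.columns:
            check(row["background_score"] in BACKGROUND_LEVELS,
                  f"background_score {row['background_score']!r} not in {sorted(BACKGROUND_LEVELS)}")
        for col in ("morphology_onset", "morphology_peak"):
            if col in records.columns:
                check(row[col] in morphology_levels,
                      f"{col} {row[col]!r} not in {morphology_levels}")
        for col in ("n_channels_onset", "n_channels_peak"):
            if col in records.columns:
                check(1 <= row[col] <= n_channels,
                      f"{col} must be in 1..{n_channels}, got {row[col]!r}")
        if {"morphology_onset", "morphology_peak", "morphology_change"} <= set(records.columns):
            if (row["morphology_onset"] in morphology_levels
                    and row["morphology_peak"] in morphology_levels):
                expected = row["morphology_onset"] != row["morphology_peak"]
                check(bool(row["morphology_change"]) == expected,
                      "morphology_change inconsistent with onset/peak categories")
        if {"n_channels_onset", "n_channels_peak"} <= set(records.columns):
            # a shrinking seizure field is unusual but not invalid
            check(row["n_channels_onset"] <= row["n_channels_peak"],
                  "n_channels_onset exceeds n_channels_peak", warning=True)
    return records, issues
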