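"""Minimal reference seizure detector and the adaptive probability-baseline
correction.

The detector mirrors the canonical SDA architecture — per-channel epoching
(8 s, overlapping), a small epoch feature vector, a linear score squashed
through a sigmoid into a seizure probability, moving-average smoothing, a
cross-channel maximum, and threshold crossing into events — with a fixed,
documented linear score instead of a trained classifier. It exists to
audit the analysis pipeline end to end; it makes no claim of clinical
detection performance. Epochs whose signal energy exceeds a cap are
pre-masked (simple high-energy artefact removal).

The adaptive baseline correction subtracts the trailing-window median of
the probability trace from each value, suppressing sustained rhythmic
artefact that elevates the baseline for long stretches while preserving
transient excursions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sps
from scipy.special import expit

from .records import DEFAULT_THRESHOLDS, DetectionEvent, ProbabilityTrace
from .simulate import BIPOLAR_MONTAGE

__all__ = [
    "DetectorConfig",
    "epoch_features",
    "reference_detector",
    "events_from_trace",
    "adaptive_baseline",
]


@dataclass
class DetectorConfig:
    """Reference-detector settings.

    The linear score combines, per 8-s epoch: log relative RMS amplitude,
    spectral flatness deficit (1 − normalized spectral entropy; rhythmic
    discharges concentrate power in few bins), low-band (0.5–4 Hz) power
    fraction, and the log prominence of the spectral peak. Weights are
    fixed constants chosen so pink-noise background scores well below 0 and
    sustained high-amplitude rhythmic activity scores above it.
    """

    epoch_len: float = 8.0
    overlap: float = 0.5
    smooth_epochs: int = 3
    thresholds: tuple[float, ...] = DEFAULT_THRESHOLDS
    known_channels: tuple[str, ...] = BIPOLAR_MONTAGE
    reference_rms: float = 25.0          # µV, typical background level
    energy_mask_rms: float = 400.0       # µV, epochs above are masked
    weights: dict = field(
        default_factory=lambda: {
            "log_rms": 2.0,
            "rhythmicity": 10.0,    # 1 - normalized spectral entropy
            "low_band_fraction": 1.5,
            "log_peak_prominence": 0.5,
            "bias": -10.3,
        }
    )

    def __post_init__(self) -> None:
        if not 0.0 <= self.overlap < 1.0:
            raise ValueError("overlap must be in [0, 1)")
        if self.epoch_len <= 0 or self.smooth_epochs < 1:
            raise ValueError("epoch_len must be > 0 and smooth_epochs >= 1")

    @property
    def epoch_step(self) -> float:
        return self.epoch_len * (1.0 - self.overlap)


def epoch_features(epoch: np.ndarray, sfreq: float) -> dict[str, float]:
    """Feature vector of one single-channel epoch (amplitudes in µV)."""
    x = np.asarray(epoch, float)
    x = x - x.mean()
    rms = float(np.sqrt(np.mean(x**2)))
    freqs, psd = sps.periodogram(x, fs=sfreq)
    freqs, psd = freqs[1:], psd[1:]  # drop DC
    total = psd.sum()
    if total <= 0:
        return {
            "rms": 0.0, "rhythmicity": 0.0, "low_band_fraction": 0.0,
            "peak_prominence": 1.0,
        }
    p = psd / total
    with np.errstate(divide="ignore", invalid="ignore"):
        entropy = float(-np.nansum(p * np.log(p)) / np.log(p.size))
    low = float(psd[(freqs >= 0.5) & (freqs <= 4.0)].sum() / total)
    med = float(np.median(psd))
    prominence = float(psd.max() / med) if med > 0 else float("inf")
    return {
        "rms": rms,
        "rhythmicity": 1.0 - entropy,
        "low_band_fraction": low,
        "peak_prominence": prominence,
    }


def _moving_average(values: np.ndarray, window: int) -> np.ndarray:
    if window <= 1:
        return values
    kernel = np.ones(window) / window
    # centred smoothing with edge padding to keep the trace length
    padded = np.pad(values, (window // 2, window - 1 - window // 2), mode="edge")
    return np.convolve(padded, kernel, mode="valid")


def reference_detector(
    samples: np.ndarray,
    channels: list[str],
    sfreq: float,
    config: DetectorConfig | None = None,
    record_id: str = "synthetic",
) -> tuple[ProbabilityTrace, dict[float, list[DetectionEvent]]]:
    """Run the reference detector over a multichannel segment.

    Returns the per-channel probability trace and the event lists at every
    configured threshold (maximal runs of the cross-channel maximum trace
    at or above the threshold, reported with onset, duration and channel of
    peak detection).
    """
    config = config or DetectorConfig()
    samples = np.atleast_2d(np.asarray(samples, float))
    unknown = [c for c in channels if c not in config.known_channels]
    if unknown:
        raise ValueError(
            f"unknown channel label(s) {unknown}; expected labels from "
            f"{config.known_channels}"
        )
    if samples.shape[0] != len(channels):
        raise ValueError(f"{samples.shape[0]} signal rows for {len(channels)} labels")

    win = int(round(config.epoch_len * sfreq))
    step = int(round(config.epoch_step * sfreq))
    n = samples.shape[1]
    if n < win:
        raise ValueError(
            f"segment ({n / sfreq:.1f} s) shorter than one epoch ({config.epoch_len} s)"
        )
    starts = np.arange(0, n - win + 1, step)
    w = config.weights
    probs = np.zeros((len(channels), starts.size))
    for c in range(len(channels)):
        for k, s0 in enumerate(starts):
            f = epoch_features(samples[c, s0 : s0 + win], sfreq)
            if f["rms"] > config.energy_mask_rms:  # high-energy artefact mask
                probs[c, k] = 0.0
                continue
            score = (
                w["log_rms"] * np.log(max(f["rms"], 1e-3) / config.reference_rms)
                + w["rhythmicity"] * f["rhythmicity"]
                + w["low_band_fraction"] * f["low_band_fraction"]
                + w["log_peak_prominence"] * np.log(max(f["peak_prominence"], 1e-12))
                + w["bias"]
            )
            probs[c, k] = expit(score)
        probs[c] = _moving_average(probs[c], config.smooth_epochs)

    trace = ProbabilityTrace(
        record_id=record_id,
        epoch_step=config.epoch_step,
        values=probs,
        channels=list(channels),
    )
    events = {
        t: events_from_trace(trace, t, record_id=record_id)
        for t in config.thresholds
    }
    return trace, events


def events_from_trace(
    trace: ProbabilityTrace, threshold: float, record_id: str | None = None
) -> list[DetectionEvent]:
    """Extract detection events (maximal runs of the cross-channel maximum
    probability at or above ``threshold``) from a probability trace."""
    record_id = record_id or trace.record_id
    summary = trace.max_over_channels()
    above = summary >= threshold
    if not above.any():
        return []
    edges = np.diff(above.astype(int))
    run_starts = list(np.where(edges == 1)[0] + 1)
    run_ends = list(np.where(edges == -1)[0] + 1)
    if above[0]:
        run_starts.insert(0, 0)
    if above[-1]:
        run_ends.append(above.size)
    events = []
    for lo, hi in zip(run_starts, run_ends):
        if trace.channels:
            block = trace.values[:, lo:hi]
            peak_channel = trace.channels[int(np.argmax(block.max(axis=1)))]
        else:
            peak_channel = ""
        events.append(
            DetectionEvent(
                record_id=record_id,
                threshold=threshold,
                start=lo * trace.epoch_step,
                duration=(hi - lo) * trace.epoch_step,
                peak_channel=peak_channel,
            )
        )
    return events


def adaptive_baseline(
    trace: ProbabilityTrace, window_minutes: float = 30.0
) -> ProbabilityTrace:
    """Subtract the local preceding probability baseline from a trace.

    Each value is replaced by ``(value − m) / (1 − m)`` clipped to [0, 1],
    where ``m`` is the median of the trailing window (ending at and
    including the current epoch). A prolonged elevated baseline — sustained
    rhythmic artefact — is suppressed, while a transient excursion above
    the local baseline is preserved (and rescaled so a full-scale
    excursion still reaches 1).

    When the trace is shorter than the window the baseline uses whatever
    history exists, with a warning.
    """
    if window_minutes <= 0:
        raise ValueError("window_minutes must be > 0")
    window_epochs = max(int(round(window_minutes * 60.0 / trace.epoch_step)), 1)
    if trace.n_epochs < window_epochs:
        warnings.warn(
            f"trace ({trace.n_epochs} epochs) shorter than the baseline "
            f"window ({window_epochs} epochs); using available history",
            stacklevel=2,
        )
    corrected = np.empty_like(trace.values)
    for c in range(trace.values.shape[0]):
        med = (
            pd.Series(trace.values[c])
            .rolling(window_epochs, min_periods=1)
            .median()
            .to_numpy()
        )
        corrected[c] = np.clip(
            (trace.values[c] - med) / np.maximum(1.0 - med, 1e-9), 0.0, 1.0
        )
    return ProbabilityTrace(
        record_id=trace.record_id,
        epoch_step=trace.epoch_step,
        values=corrected,
        channels=list(trace.channels),
    )
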