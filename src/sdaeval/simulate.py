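"""Synthetic cohorts, false-detection streams and toy multichannel EEG.

Everything needed to exercise the analysis pipeline with known ground
truth:

* :func:`generate_cohort` — babies with per-baby random intercepts and a
  planted logistic detectability model over the 10-feature seizure schema.
  Each seizure draws a latent detector score once, so its detected flags
  are nested across the threshold grid, and the probability of detection
  at every threshold follows exactly the planted random-intercept logistic
  model (same slopes, threshold-shifted intercept).
* :func:`generate_fd_stream` — patient-clustered artefact streams with
  category-specific survival across thresholds.
* :func:`synthesize_eeg` — toy seizure and artefact waveforms on a
  pink-noise background. These are caricatures for detector plumbing, not
  physiological EEG.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .records import (
    DEFAULT_THRESHOLDS,
    FD_CATEGORIES,
    NO_ARTEFACT_SUBCATEGORIES,
    DetectionEvent,
    FalseDetectionRecord,
    RecordMeta,
    SeizureAnnotation,
)

__all__ = [
    "BIPOLAR_MONTAGE",
    "CohortConfig",
    "generate_cohort",
    "FdStreamConfig",
    "generate_fd_stream",
    "EegSegmentSpec",
    "synthesize_eeg",
    "pink_noise",
]

#: Default neonatal bipolar montage (9 electrodes of the adapted 10:20).
BIPOLAR_MONTAGE: tuple[str, ...] = (
    "F4-C4", "C4-O2", "F3-C3", "C3-O1", "T4-C4", "C4-Cz", "Cz-C3", "C3-T3",
)

_MORPHOLOGIES = ("RDD", "RDT", "RDA", "S/SH", "SH+W/SP+W")


@dataclass
class CohortConfig:
    """Study conditions for a synthetic seizure cohort.

    Defaults emulate a two-centre audit cohort: 20 babies with around 20
    seizures each, lognormal seizure durations (median ≈ 1 min) and peak
    amplitudes (median ≈ 100 µV peak-to-trough), mostly rhythmic-delta
    onset morphology that often evolves to sharp-and-slow-wave complexes
    at peak, and 1–8 involved channels with the field widening towards the
    seizure peak. The planted detectability effects sit at the odds-ratio
    scale typical of such audits: OR 1.02 per second of duration and per
    µV of amplitude, about 1.4 per extra channel at peak, and graded odds
    for increasing rhythmicity.

    ``intercept=None`` centres the linear predictor so the latent detector
    score has median ≈ ``target_median_score``.
    """

    n_babies: int = 20
    seizures_per_baby: int = 20
    poisson_seizure_counts: bool = False
    thresholds: tuple[float, ...] = DEFAULT_THRESHOLDS
    random_intercept_sd: float = 1.0
    planted_effects: dict = field(
        default_factory=lambda: {
            "duration": float(np.log(1.02)),
            "peak_amplitude": float(np.log(1.02)),
            "n_channels_peak": float(np.log(1.4)),
            "rhythmicity_2": float(np.log(2.5)),
            "rhythmicity_3": float(np.log(5.0)),
            "morphology_change": float(np.log(2.3)),
        }
    )
    intercept: float | None = None
    target_median_score: float = 0.5
    duration_log_mean: float = 4.0     # log seconds (median ≈ 55 s)
    duration_log_sd: float = 0.9
    amplitude_log_mean: float = 4.6    # log µV (median ≈ 100 µV)
    amplitude_log_sd: float = 0.6
    rhythmicity_probs: tuple[float, float, float] = (0.25, 0.40, 0.35)
    background_probs: tuple[float, float, float] = (0.30, 0.45, 0.25)
    n_channels: int = 8
    record_hours_log_mean: float = 4.1  # log hours (median ≈ 60 h)
    record_hours_log_sd: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_babies < 2:
            raise ValueError("n_babies must be >= 2")
        t = np.asarray(self.thresholds, float)
        if t.size < 1 or np.any(t <= 0) or np.any(t >= 1) or np.any(np.diff(t) <= 0):
            raise ValueError("thresholds must be strictly increasing in (0, 1)")
        for probs in (self.rhythmicity_probs, self.background_probs):
            if len(probs) != 3 or abs(sum(probs) - 1.0) > 1e-9 or min(probs) < 0:
                raise ValueError(f"level probabilities must be a 3-simplex, got {probs}")
        if self.random_intercept_sd < 0:
            raise ValueError("random_intercept_sd must be >= 0")


#: Onset-morphology marginal and onset -> peak transition rows. Rhythmic
#: delta dominates at onset; it frequently evolves into sharp-and-slow-wave
#: complexes at the seizure peak.
_ONSET_PROBS = np.array([0.55, 0.10, 0.02, 0.13, 0.20])
_TRANSITION = {
    "RDD":       np.array([0.45, 0.05, 0.00, 0.15, 0.35]),
    "RDT":       np.array([0.10, 0.50, 0.05, 0.10, 0.25]),
    "RDA":       np.array([0.05, 0.15, 0.50, 0.10, 0.20]),
    "S/SH":      np.array([0.05, 0.02, 0.00, 0.58, 0.35]),
    "SH+W/SP+W": np.array([0.03, 0.02, 0.00, 0.10, 0.85]),
}


def _linear_predictor(features: pd.DataFrame, effects: dict, intercept: float) -> np.ndarray:
    eta = np.full(len(features), intercept)
    for name, beta in effects.items():
        if beta == 0.0:
            continue
        if name.startswith("rhythmicity_"):
            level = int(name.rsplit("_", 1)[1])
            eta += beta * (features["rhythmicity"].to_numpy() == level)
        elif name.startswith("background_"):
            level = int(name.rsplit("_", 1)[1])
            eta += beta * (features["background_score"].to_numpy() == level)
        elif name == "morphology_change":
            eta += beta * features["morphology_change"].to_numpy(float)
        else:
            eta += beta * features[name].to_numpy(float)
    return eta


def generate_cohort(
    config: CohortConfig | None = None, seed: int | None = None
) -> tuple[list[RecordMeta], pd.DataFrame, dict]:
    """Generate a cohort of babies with scored seizures and planted
    per-threshold detection flags.

    Each seizure i of baby j draws a latent detector score

        s_ij = expit(eta_ij + b_j + eps_ij),
        eta_ij = intercept + beta' x_ij,  b_j ~ N(0, sd^2),
        eps_ij ~ Logistic(0, 1),

    once; ``detected_{t}`` is ``s_ij >= t``, so flags are non-increasing
    across the ordered threshold grid, and P(detected at t | b_j) =
    expit((intercept − logit t) + beta' x_ij + b_j) — the planted
    random-intercept logistic model at every threshold.

    Returns (records, feature table, ground truth dict). The ground truth
    carries the planted coefficients, realized random intercepts and latent
    scores.
    """
    config = config or CohortConfig()
    rng = np.random.default_rng(config.seed if seed is None else seed)

    counts = (
        np.maximum(rng.poisson(config.seizures_per_baby, config.n_babies), 1)
        if config.poisson_seizure_counts
        else np.full(config.n_babies, config.seizures_per_baby)
    )
    baby_ids = [f"baby-{j + 1:02d}" for j in range(config.n_babies)]
    rows = []
    for j, baby in enumerate(baby_ids):
        for k in range(counts[j]):
            onset_idx = rng.choice(5, p=_ONSET_PROBS)
            onset = _MORPHOLOGIES[onset_idx]
            peak = _MORPHOLOGIES[rng.choice(5, p=_TRANSITION[onset])]
            n_onset = int(min(1 + rng.geometric(0.45) - 1, config.n_channels))
            n_peak = int(min(n_onset + rng.poisson(1.2), config.n_channels))
            f_mid = rng.lognormal(np.log(1.5), 0.35)
            f_start = f_mid * rng.lognormal(0.0, 0.25)
            f_end = f_mid * rng.lognormal(0.0, 0.25)
            rows.append(
                {
                    "seizure_id": f"{baby}-sz{k + 1:03d}",
                    "baby_id": baby,
                    "peak_amplitude": rng.lognormal(
                        config.amplitude_log_mean, config.amplitude_log_sd
                    ),
                    "rhythmicity": 1 + rng.choice(3, p=config.rhythmicity_probs),
                    "background_score": 1 + rng.choice(3, p=config.background_probs),
                    "morphology_onset": onset,
                    "morphology_peak": peak,
                    "duration": rng.lognormal(
                        config.duration_log_mean, config.duration_log_sd
                    ),
                    "frequency_variability": float(
                        np.std([f_start, f_mid, f_end], ddof=1)
                    ),
                    "morphology_change": onset != peak,
                    "n_channels_onset": n_onset,
                    "n_channels_peak": n_peak,
                }
            )
    features = pd.DataFrame(rows)

    eta_no_intercept = _linear_predictor(features, config.planted_effects, 0.0)
    intercept = (
        config.intercept
        if config.intercept is not None
        else float(
            logit(config.target_median_score) - np.median(eta_no_intercept)
        )
    )
    eta = eta_no_intercept + intercept
    b = rng.normal(0.0, config.random_intercept_sd, config.n_babies)
    b_per_row = b[np.repeat(np.arange(config.n_babies), counts)]
    eps = rng.logistic(0.0, 1.0, len(features))
    score = expit(eta + b_per_row + eps)
    for t in config.thresholds:
        features[f"detected_{t}"] = score >= t

    records = [
        RecordMeta(
            record_id=f"rec-{baby}",
            baby_id=baby,
            duration_hours=float(
                rng.lognormal(config.record_hours_log_mean, config.record_hours_log_sd)
            ),
            group="seizure",
        )
        for baby in baby_ids
    ]
    truth = {
        "planted_effects": dict(config.planted_effects),
        "intercept": intercept,
        "random_intercepts": dict(zip(baby_ids, b.tolist())),
        "latent_scores": score,
        "thresholds": tuple(config.thresholds),
        "random_intercept_sd": config.random_intercept_sd,
    }
    return records, features, truth


# --- patient-clustered false-detection streams ----------------------------

@dataclass
class FdStreamConfig:
    """Clustered artefact-stream conditions.

    ``category_rates`` are cohort-level false detections per hour at the
    most sensitive threshold; defaults approximate an audited 800-FD
    distribution over ~1260 h. ``survival`` maps each category to the
    probability that one of its events still exceeds each threshold of the
    grid (non-increasing; rhythmic respiration survives raising the
    threshold far better than intermittent sweat). ``concentration`` is the
    Dirichlet parameter distributing each category's events over patients:
    small values concentrate a category in few patients, as observed for
    respiration and sweat artefact.
    """

    n_patients: int = 20
    hours_per_patient: float = 63.0
    thresholds: tuple[float, ...] = DEFAULT_THRESHOLDS
    category_rates: dict = field(
        default_factory=lambda: {
            "respiration": 0.22,
            "ecg_pulse": 0.027,
            "bad_electrode": 0.017,
            "movement_handling": 0.045,
            "sweat": 0.127,
            "unclassified_artefact": 0.023,
            "no_artefact": 0.175,
        }
    )
    survival: dict = field(
        default_factory=lambda: {
            "respiration": (1.0, 0.90, 0.80),
            "ecg_pulse": (1.0, 1.0, 1.0),
            "bad_electrode": (1.0, 0.52, 0.19),
            "movement_handling": (1.0, 0.28, 0.07),
            "sweat": (1.0, 0.61, 0.09),
            "unclassified_artefact": (1.0, 0.66, 0.34),
            "no_artefact": (1.0, 0.43, 0.21),
        }
    )
    concentration: float = 0.3
    no_artefact_subcategory_probs: dict = field(
        default_factory=lambda: {
            "highly_rhythmic": 0.60,
            "normal_background": 0.28,
            "sharp_waves": 0.09,
            "low_amplitude": 0.03,
        }
    )
    seed: int = 0

    def __post_init__(self) -> None:
        for cat, rate in self.category_rates.items():
            if cat not in FD_CATEGORIES:
                raise ValueError(f"unknown category {cat!r}")
            if rate < 0:
                raise ValueError(f"rate for {cat!r} must be >= 0")
        for cat, surv in self.survival.items():
            s = np.asarray(surv, float)
            if len(s) != len(self.thresholds) or np.any(np.diff(s) > 1e-12) or (
                np.any(s < 0) or np.any(s > 1)
            ):
                raise ValueError(
                    f"survival profile for {cat!r} must be non-increasing in "
                    f"[0, 1] with one entry per threshold, got {surv}"
                )
        subs = self.no_artefact_subcategory_probs
        if set(subs) - set(NO_ARTEFACT_SUBCATEGORIES) or abs(sum(subs.values()) - 1) > 1e-9:
            raise ValueError("no-artefact subcategory probabilities must sum to 1")


def generate_fd_stream(
    config: FdStreamConfig | None = None, seed: int | None = None
) -> dict[float, list[FalseDetectionRecord]]:
    """Draw a patient-clustered false-detection stream.

    For each category: the cohort-level count is Poisson(rate × total
    hours); events land on patients with Dirichlet(concentration) weights;
    each event draws one latent uniform level so the lists at higher
    thresholds are subsets of the most sensitive list (an event survives
    threshold index k iff its level <= survival[k]).

    Returns a dict threshold -> records at that threshold.
    """
    config = config or FdStreamConfig()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    total_hours = config.n_patients * config.hours_per_patient
    patients = [f"patient-{j + 1:02d}" for j in range(config.n_patients)]
    subs = list(config.no_artefact_subcategory_probs)
    sub_p = np.array([config.no_artefact_subcategory_probs[s] for s in subs])

    out: dict[float, list[FalseDetectionRecord]] = {t: [] for t in config.thresholds}
    for category in sorted(config.category_rates):
        rate = config.category_rates[category]
        n = rng.poisson(rate * total_hours)
        if n == 0:
            continue
        weights = rng.dirichlet(np.full(config.n_patients, config.concentration))
        owners = rng.choice(config.n_patients, size=n, p=weights)
        levels = rng.uniform(0.0, 1.0, size=n)
        starts = rng.uniform(0.0, config.hours_per_patient * 3600.0 - 60.0, size=n)
        survival = np.asarray(config.survival[category], float)
        for i in range(n):
            sub = (
                subs[rng.choice(len(subs), p=sub_p)]
                if category == "no_artefact"
                else None
            )
            for k, t in enumerate(config.thresholds):
                if levels[i] <= survival[k]:
                    out[t].append(
                        FalseDetectionRecord(
                            DetectionEvent(
                                record_id=patients[owners[i]],
                                threshold=t,
                                start=float(starts[i]),
                                duration=30.0,
                            ),
                            category,
                            background_subcategory=sub,
                        )
                    )
    return out


# --- toy multichannel EEG -------------------------------------------------

@dataclass
class EegSegmentSpec:
    """Specification of one synthetic EEG segment.

    The event of the given ``kind`` spans ``duration`` seconds on the first
    ``n_event_channels`` channels, flanked by ``padding`` seconds of
    pink-noise background on both sides. ``amplitude`` is the planted
    peak-to-trough envelope in µV. ``rhythmicity`` (1–3) controls the
    per-second frequency jitter (3 = highly rhythmic, minimal jitter);
    ``evolve_morphology`` shifts the seizure waveform from near-sinusoidal
    delta to spike-and-slow-wave harmonics towards the peak.
    """

    kind: str = "seizure"
    duration: float = 60.0
    padding: float = 30.0
    channels: tuple[str, ...] = BIPOLAR_MONTAGE
    n_event_channels: int = len(BIPOLAR_MONTAGE)
    amplitude: float = 100.0
    base_frequency: float = 1.5
    rhythmicity: int = 3
    evolve_morphology: bool = False
    background_rms: float = 25.0
    sfreq: float = 256.0
    seed: int = 0

    def __post_init__(self) -> None:
        kinds = (
            "seizure", "background", "respiration_artefact", "sweat_artefact",
            "pulse_artefact", "movement_artefact",
        )
        if self.kind not in kinds:
            raise ValueError(f"unsupported segment kind {self.kind!r}; expected {kinds}")
        if self.duration <= 0 or self.amplitude <= 0:
            raise ValueError("duration and amplitude must be > 0")
        if not 1 <= self.n_event_channels <= len(self.channels):
            raise ValueError("n_event_channels out of range")
        if self.rhythmicity not in (1, 2, 3):
            raise ValueError("rhythmicity must be 1, 2 or 3")


#: Per-second frequency jitter SD (Hz) by rhythmicity level.
FREQ_JITTER_SD = {1: 0.50, 2: 0.25, 3: 0.06}


def pink_noise(n: int, rng: np.random.Generator) -> np.ndarray:
    """Unit-RMS 1/f noise via spectral shaping."""
    white = rng.standard_normal(n)
    spectrum = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n)
    freqs[0] = freqs[1] if n > 1 else 1.0
    shaped = np.fft.irfft(spectrum / np.sqrt(freqs), n)
    return shaped / shaped.std()


def _fm_oscillation(
    duration: float, sfreq: float, f0: float, jitter_sd: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Phase-continuous oscillation with per-second frequency jitter.
    Returns (phase, instantaneous frequency per sample)."""
    n = int(round(duration * sfreq))
    n_seconds = int(np.ceil(duration))
    f_per_sec = np.maximum(f0 + rng.normal(0.0, jitter_sd, n_seconds), 0.2)
    f_inst = np.repeat(f_per_sec, int(sfreq))[:n]
    if f_inst.size < n:
        f_inst = np.pad(f_inst, (0, n - f_inst.size), mode="edge")
    phase = 2.0 * np.pi * np.cumsum(f_inst) / sfreq
    return phase, f_inst


def _seizure_waveform(spec: EegSegmentSpec, rng: np.random.Generator) -> np.ndarray:
    n = int(round(spec.duration * spec.sfreq))
    phase, _ = _fm_oscillation(
        spec.duration, spec.sfreq, spec.base_frequency,
        FREQ_JITTER_SD[spec.rhythmicity], rng,
    )
    base = np.sin(phase)
    if spec.evolve_morphology:
        # ramp in sharpening harmonics: delta -> spike-and-slow-wave
        ramp = np.linspace(0.0, 1.0, n)
        sharp = np.sin(2.0 * phase) * 0.5 + np.sin(3.0 * phase) * 0.3
        base = (1.0 - 0.5 * ramp) * base + ramp * sharp
        base = base / np.max(np.abs(base))
    envelope = np.sin(np.linspace(0.0, np.pi, n)) ** 0.5  # rise, plateau, fall
    return 0.5 * spec.amplitude * envelope * base


def _artefact_waveform(spec: EegSegmentSpec, rng: np.random.Generator) -> np.ndarray:
    n = int(round(spec.duration * spec.sfreq))
    t = np.arange(n) / spec.sfreq
    half = 0.5 * spec.amplitude
    if spec.kind == "respiration_artefact":
        # sustained, highly rhythmic slow sinusoid
        phase, _ = _fm_oscillation(spec.duration, spec.sfreq, 1.0, 0.03, rng)
        return half * np.sin(phase)
    if spec.kind == "sweat_artefact":
        # intermittent semi-rhythmic slow drift: slow FM sine gated by bursts
        phase, _ = _fm_oscillation(spec.duration, spec.sfreq, 0.35, 0.12, rng)
        gate = (pink_noise(n, rng) > 0.1).astype(float)
        from scipy.ndimage import uniform_filter1d
        gate = uniform_filter1d(gate, int(2 * spec.sfreq))
        return half * gate * np.sin(phase)
    if spec.kind == "pulse_artefact":
        # cardiac-rate impulse train leaking rhythmic delta
        heart_rate = 2.2  # Hz, ~130 bpm
        beat_phase = (t * heart_rate) % 1.0
        kernel = np.exp(-((beat_phase - 0.15) ** 2) / (2 * 0.05**2))
        return half * (kernel - kernel.mean()) / np.max(np.abs(kernel))
    if spec.kind == "movement_artefact":
        # sparse high-amplitude broadband bursts
        burst = np.zeros(n)
        n_bursts = max(1, int(spec.duration / 8))
        for _ in range(n_bursts):
            c = rng.integers(0, n)
            w = int(rng.uniform(0.5, 2.0) * spec.sfreq)
            lo, hi = max(c - w, 0), min(c + w, n)
            burst[lo:hi] = rng.standard_normal(hi - lo)
        return half * burst
    raise ValueError(f"unsupported kind {spec.kind!r}")  # pragma: no cover


def synthesize_eeg(
    spec: EegSegmentSpec, seed: int | None = None
) -> tuple[np.ndarray, list[str], SeizureAnnotation | None]:
    """Synthesize a multichannel EEG segment (µV), returning
    ``(samples, channel labels, ground-truth annotation or None)``.

    The event occupies ``[padding, padding + duration)`` on the first
    ``n_event_channels`` channels; the annotation is returned for seizure
    segments only (artefacts are, by definition, not seizures).
    """
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    total = spec.duration + 2.0 * spec.padding
    n = int(round(total * spec.sfreq))
    samples = np.stack(
        [spec.background_rms * pink_noise(n, rng) for _ in spec.channels]
    )
    if spec.kind != "background":
        wave = (
            _seizure_waveform(spec, rng)
            if spec.kind == "seizure"
            else _artefact_waveform(spec, rng)
        )
        lo = int(round(spec.padding * spec.sfreq))
        for ch in range(spec.n_event_channels):
            gain = 1.0 if ch == 0 else rng.uniform(0.6, 1.0)
            samples[ch, lo : lo + wave.size] += gain * wave
    annotation = (
        SeizureAnnotation(
            record_id="synthetic", start=spec.padding, end=spec.padding + spec.duration
        )
        if spec.kind == "seizure"
        else None
    )
    return samples, list(spec.channels), annotation
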