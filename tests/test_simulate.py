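"""Synthetic-data generator: determinism, threshold nesting, planted
rates, clustering and waveform ground truth."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

from sdaeval import (
    CohortConfig,
    EegSegmentSpec,
    FdStreamConfig,
    generate_cohort,
    generate_fd_stream,
    synthesize_eeg,
)
from sdaeval.simulate import FREQ_JITTER_SD, _fm_oscillation, pink_noise


class TestGenerateCohort:
    def test_same_seed_identical_output(self):
        cfg = CohortConfig(n_babies=5, seizures_per_baby=8, seed=3)
        _, f1, t1 = generate_cohort(cfg)
        _, f2, t2 = generate_cohort(cfg)
        pd.testing.assert_frame_equal(f1, f2)
        assert t1["intercept"] == t2["intercept"]

    def test_detected_flags_nested_across_thresholds(self):
        _, frame, _ = generate_cohort(CohortConfig(seed=4))
        assert (frame["detected_0.6"] <= frame["detected_0.5"]).all()
        assert (frame["detected_0.5"] <= frame["detected_0.4"]).all()

    def test_null_model_marginal_rates(self):
        """With no planted effects, intercept 0 and no between-baby
        variance, P(detected at t) = P(logistic noise >= logit t) = 1 - t."""
        cfg = CohortConfig(
            n_babies=20, seizures_per_baby=100, random_intercept_sd=0.0,
            planted_effects={}, intercept=0.0, seed=5,
        )
        _, frame, _ = generate_cohort(cfg)
        n = len(frame)
        rates = [frame[f"detected_{t}"].mean() for t in (0.4, 0.5, 0.6)]
        assert rates[0] > rates[1] > rates[2]
        for t, rate in zip((0.4, 0.5, 0.6), rates):
            se = np.sqrt((1 - t) * t / n)
            assert abs(rate - (1 - t)) <= 3 * se

    def test_zero_intercept_sd_no_overdispersion(self):
        """With sigma = 0, between-baby variation in detection rate is
        binomial only: the overdispersion statistic stays within chi-square
        bounds."""
        cfg = CohortConfig(
            n_babies=20, seizures_per_baby=50, random_intercept_sd=0.0,
            planted_effects={}, intercept=0.0, seed=6,
        )
        _, frame, _ = generate_cohort(cfg)
        p_hat = frame["detected_0.5"].mean()
        stat = 0.0
        for _, sub in frame.groupby("baby_id"):
            n_j = len(sub)
            k_j = sub["detected_0.5"].sum()
            stat += (k_j - n_j * p_hat) ** 2 / (n_j * p_hat * (1 - p_hat))
        from scipy.stats import chi2

        assert stat < chi2.ppf(0.995, df=19)

    def test_planted_model_controls_detection_probability(self):
        """Seizures in the top duration quartile are detected more often
        than those in the bottom quartile when only duration is planted."""
        cfg = CohortConfig(
            n_babies=20, seizures_per_baby=50,
            planted_effects={"duration": np.log(1.02)},
            random_intercept_sd=0.5, seed=7,
        )
        _, frame, _ = generate_cohort(cfg)
        q1, q3 = frame["duration"].quantile([0.25, 0.75])
        low = frame[frame["duration"] <= q1]["detected_0.5"].mean()
        high = frame[frame["duration"] >= q3]["detected_0.5"].mean()
        assert high > low + 0.2

    def test_ground_truth_carries_planted_parameters(self):
        cfg = CohortConfig(n_babies=4, seizures_per_baby=5, seed=8)
        records, frame, truth = generate_cohort(cfg)
        assert truth["planted_effects"]["duration"] == pytest.approx(np.log(1.02))
        assert len(truth["random_intercepts"]) == 4
        assert len(truth["latent_scores"]) == len(frame)
        assert len(records) == 4
        assert all(r.duration_hours > 0 for r in records)

    def test_feature_table_passes_schema_validation(self):
        from sdaeval import validate_feature_table

        _, frame, _ = generate_cohort(CohortConfig(n_babies=6, seizures_per_baby=10, seed=9))
        _, issues = validate_feature_table(frame)
        assert [i for i in issues if not i.startswith("warning:")] == []

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            CohortConfig(n_babies=1)
        with pytest.raises(ValueError):
            CohortConfig(thresholds=(0.6, 0.4))
        with pytest.raises(ValueError):
            CohortConfig(rhythmicity_probs=(0.5, 0.5, 0.5))


class TestFdStream:
    def test_determinism_and_nesting(self):
        cfg = FdStreamConfig(seed=3)
        s1 = generate_fd_stream(cfg)
        s2 = generate_fd_stream(cfg)
        assert {t: len(v) for t, v in s1.items()} == {t: len(v) for t, v in s2.items()}
        # events at a higher threshold are a subset of the lower threshold
        def keys(recs):
            return {(r.event.record_id, r.event.start, r.category) for r in recs}

        assert keys(s1[0.6]) <= keys(s1[0.5]) <= keys(s1[0.4])

    def test_zero_rates_empty_stream(self):
        cfg = FdStreamConfig(category_rates={"sweat": 0.0}, survival={"sweat": (1, 1, 1)})
        stream = generate_fd_stream(cfg)
        assert all(len(v) == 0 for v in stream.values())

    def test_retention_ordering_respiration_vs_sweat(self):
        """Planted survival (1, .9, .8) for respiration vs (1, .61, .09)
        for sweat reproduces the gentle-vs-sharp drop-off."""
        base = {"respiration": 0, "sweat": 0}
        top = {"respiration": 0, "sweat": 0}
        for seed in range(5):  # pool streams for a tight binomial check
            stream = generate_fd_stream(FdStreamConfig(seed=seed))
            for cat in base:
                base[cat] += sum(r.category == cat for r in stream[0.4])
                top[cat] += sum(r.category == cat for r in stream[0.6])

        retention = {c: top[c] / base[c] for c in base}
        assert retention["respiration"] > retention["sweat"]
        # empirical retention near the planted survival (binomial 3 SE)
        se = np.sqrt(0.8 * 0.2 / base["respiration"])
        assert abs(retention["respiration"] - 0.8) <= 3 * se
        se_sweat = np.sqrt(0.09 * 0.91 / base["sweat"])
        assert abs(retention["sweat"] - 0.09) <= 3 * se_sweat

    def test_high_concentration_top_patient_dominates(self):
        cfg = FdStreamConfig(concentration=0.05, seed=13)
        stream = generate_fd_stream(cfg)
        from sdaeval import patient_concentration

        _, _, share = patient_concentration(stream[0.4], "respiration")
        assert share > 50.0

    def test_category_shares_match_planted_rates(self):
        """Aggregated shares at the base threshold track the planted
        Poisson rates within 3 SE."""
        cfg = FdStreamConfig(seed=17, hours_per_patient=200.0)
        stream = generate_fd_stream(cfg)
        total_rate = sum(cfg.category_rates.values())
        n = len(stream[0.4])
        for cat in ("respiration", "sweat", "no_artefact"):
            expected = cfg.category_rates[cat] / total_rate
            observed = sum(r.category == cat for r in stream[0.4]) / n
            se = np.sqrt(expected * (1 - expected) / n)
            assert abs(observed - expected) <= 3 * se

    def test_invalid_survival_profile_rejected(self):
        with pytest.raises(ValueError, match="non-increasing"):
            FdStreamConfig(survival={"sweat": (0.5, 0.9, 1.0)})


class TestSynthesizeEeg:
    def test_determinism(self):
        spec = EegSegmentSpec(kind="seizure", duration=20, padding=5, seed=2)
        x1, _, _ = synthesize_eeg(spec)
        x2, _, _ = synthesize_eeg(spec)
        np.testing.assert_array_equal(x1, x2)

    def test_shapes_channels_annotation(self):
        spec = EegSegmentSpec(
            kind="seizure", duration=30, padding=10, n_event_channels=3, seed=1
        )
        x, channels, ann = synthesize_eeg(spec)
        assert x.shape == (8, int(50 * spec.sfreq))
        assert len(channels) == 8
        assert (ann.start, ann.end) == (10.0, 40.0)

    def test_artefacts_have_no_annotation(self):
        for kind in ("background", "respiration_artefact", "sweat_artefact",
                     "pulse_artefact", "movement_artefact"):
            spec = EegSegmentSpec(kind=kind, duration=20, padding=5, seed=1)
            _, _, ann = synthesize_eeg(spec)
            assert ann is None

    def test_event_confined_to_event_channels(self):
        spec = EegSegmentSpec(
            kind="seizure", duration=30, padding=10, amplitude=300,
            n_event_channels=1, seed=4,
        )
        x, _, _ = synthesize_eeg(spec)
        lo, hi = int(10 * spec.sfreq), int(40 * spec.sfreq)
        event_power = x[0, lo:hi].std()
        other_power = x[4, lo:hi].std()
        assert event_power > 3 * other_power

    def test_rhythmicity_controls_frequency_jitter(self):
        rng1 = np.random.default_rng(5)
        rng3 = np.random.default_rng(5)
        _, f1 = _fm_oscillation(120, 256.0, 1.5, FREQ_JITTER_SD[1], rng1)
        _, f3 = _fm_oscillation(120, 256.0, 1.5, FREQ_JITTER_SD[3], rng3)
        assert np.std(f1[:: 256]) > np.std(f3[:: 256])

    def test_pink_noise_spectrum_slope(self, rng):
        """Spectral power falls with frequency (1/f), unlike white noise."""
        x = pink_noise(int(120 * 256), rng)
        from scipy import signal as sps

        f, p = sps.welch(x, fs=256.0, nperseg=4096)
        low = p[(f > 0.5) & (f < 2)].mean()
        high = p[(f > 20) & (f < 40)].mean()
        assert low > 10 * high

    def test_unsupported_kind_rejected(self):
        with pytest.raises(ValueError, match="unsupported"):
            EegSegmentSpec(kind="chewing")
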