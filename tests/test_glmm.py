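"""Random-intercept logistic regression: oracle equivalence, external
cross-check, inference helpers and AUC machinery."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from sdaeval import (
    CohortConfig,
    RandomInterceptLogit,
    SeparationError,
    compare_auc,
    delong_auc,
    fit_glmm,
    generate_cohort,
    mann_whitney,
    odds_ratio_ci,
)


def _cohort_frame(**kwargs):
    defaults = dict(
        n_babies=12, seizures_per_baby=15, random_intercept_sd=0.8,
        planted_effects={"duration": np.log(1.02), "peak_amplitude": np.log(1.01)},
        seed=42,
    )
    defaults.update(kwargs)
    _, frame, _ = generate_cohort(CohortConfig(**defaults))
    frame["detected"] = frame["detected_0.5"].astype(float)
    return frame


class TestFitting:
    def test_sigma_zero_matches_plain_logistic(self):
        """With no between-baby variance the marginal model collapses to
        ordinary logistic regression."""
        frame = _cohort_frame(
            n_babies=20, seizures_per_baby=100, random_intercept_sd=0.0,
            planted_effects={"duration": np.log(1.02)}, seed=7,
        )
        model = RandomInterceptLogit(frame, "detected", ["duration"], "baby_id")
        boundary = model.fit(fixed_sigma=0.0)
        X = np.column_stack([np.ones(len(frame)), frame["duration"]])
        oracle = sm.Logit(frame["detected"], X).fit(disp=0)
        assert np.abs(boundary.params - np.asarray(oracle.params)).max() < 1e-3
        assert boundary.loglik == pytest.approx(oracle.llf, abs=1e-6)
        # the free fit collapses to (or stays near) the boundary
        free = model.fit()
        assert free.random_intercept_sd < 0.15
        assert np.abs(free.params - np.asarray(oracle.params)).max() < 0.05

    def test_loglik_dominates_nested_plain_logistic(self):
        """The marginal ML optimum cannot be worse than the sigma = 0
        boundary, which is exactly the plain logistic fit."""
        frame = _cohort_frame()
        fit = fit_glmm(frame, "detected", ["duration"], "baby_id")
        X = np.column_stack([np.ones(len(frame)), frame["duration"]])
        oracle = sm.Logit(frame["detected"], X).fit(disp=0)
        assert fit.loglik >= oracle.llf - 1e-6

    def test_matches_frozen_external_glmm_fit(self):
        """Cross-check against a frozen fit of the identical dataset by an
        independent GLMM implementation (lme4::glmer, 15-node adaptive
        quadrature)."""
        frame = _cohort_frame()
        fit = fit_glmm(frame, "detected", ["duration", "peak_amplitude"], "baby_id")
        external_coef = np.array([-1.839718522504, 0.019254478013, 0.008983558537])
        external_se = np.array([0.649392262206, 0.005001034508, 0.003334648631])
        assert np.abs(fit.params - external_coef).max() < 1e-3
        assert fit.random_intercept_sd == pytest.approx(1.328737, abs=1e-3)
        assert fit.loglik == pytest.approx(-95.22742, abs=1e-3)
        np.testing.assert_allclose(fit.bse, external_se, rtol=0.05)

    def test_quadrature_stability_15_vs_31_nodes(self):
        frame = _cohort_frame()
        f15 = RandomInterceptLogit(frame, "detected", ["duration"], "baby_id", n_quad=15).fit()
        f31 = RandomInterceptLogit(frame, "detected", ["duration"], "baby_id", n_quad=31).fit()
        assert np.abs(f15.params - f31.params).max() < 1e-4
        assert abs(f15.random_intercept_sd - f31.random_intercept_sd) < 1e-4

    def test_constant_outcome_rejected(self):
        frame = _cohort_frame()
        frame["detected"] = 1.0
        with pytest.raises(ValueError, match="constant"):
            fit_glmm(frame, "detected", ["duration"], "baby_id")

    def test_complete_separation_names_term(self):
        frame = _cohort_frame()
        frame["leak"] = frame["detected"] * 10.0 - 5.0
        with pytest.raises(SeparationError, match="leak"):
            fit_glmm(frame, "detected", ["leak"], "baby_id")

    def test_single_group_rejected(self):
        frame = _cohort_frame()
        frame["baby_id"] = "b1"
        with pytest.raises(ValueError, match="2 groups"):
            fit_glmm(frame, "detected", ["duration"], "baby_id")

    def test_planted_coefficient_recovery_single_replicate(self):
        frame = _cohort_frame(
            n_babies=20, seizures_per_baby=20, random_intercept_sd=1.0,
            planted_effects={"duration": np.log(1.02)}, seed=1,
        )
        fit = fit_glmm(frame, "detected", ["duration"], "baby_id")
        lo, hi = fit.conf_int()[1]
        assert lo <= np.log(1.02) <= hi

    def test_categorical_term_block_pvalue(self):
        frame = _cohort_frame(n_babies=15, seizures_per_baby=25, seed=9)
        from sdaeval import FixedEffect

        eff = FixedEffect("rhythmicity", categorical=True, reference=1)
        fit = fit_glmm(frame, "detected", [eff, "duration"], "baby_id")
        p = fit.term_pvalue("rhythmicity")
        assert 0.0 <= p <= 1.0
        assert "rhythmicity[2]" in fit.names and "rhythmicity[3]" in fit.names


class TestOddsRatioCi:
    def test_closed_form(self):
        or_, lo, hi = odds_ratio_ci(0.0, 0.1)
        assert or_ == pytest.approx(1.0)
        assert lo == pytest.approx(0.822, abs=5e-4)
        assert hi == pytest.approx(1.217, abs=5e-4)

    def test_exponential_identity(self):
        or_, lo, hi = odds_ratio_ci(np.log(2.0), 0.3)
        assert or_ == pytest.approx(2.0)
        assert lo < 2.0 < hi

    def test_duration_odds_ratio_scale(self):
        # log-odds 0.0198 per second of seizure duration -> OR 1.02
        or_, _, _ = odds_ratio_ci(0.0198, 0.003)
        assert or_ == pytest.approx(1.02, abs=5e-4)

    def test_nonpositive_se_rejected(self):
        with pytest.raises(ValueError):
            odds_ratio_ci(0.5, 0.0)


def bruteforce_auc(y, score):
    """All-pairs concordance count: ties count one half."""
    pos = score[y == 1]
    neg = score[y == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestAuc:
    def test_perfect_separation_auc_one(self):
        y = np.array([0, 0, 1, 1])
        auc, lo, hi = delong_auc(y, np.array([0.1, 0.2, 0.8, 0.9]))
        assert auc == 1.0

    def test_hand_computed_four_point_roc(self):
        y = np.array([1, 0, 1, 0])
        score = np.array([0.9, 0.6, 0.7, 0.2])
        auc, _, _ = delong_auc(y, score)
        assert auc == pytest.approx(bruteforce_auc(y, score)) == 1.0  # 4/4 pairs

        score2 = np.array([0.9, 0.6, 0.5, 0.2])
        auc2, _, _ = delong_auc(y, score2)
        assert auc2 == pytest.approx(bruteforce_auc(y, score2)) == 0.75

    def test_equals_bruteforce_concordance_on_random_scores(self, rng):
        for n in (20, 101, 200):
            y = rng.integers(0, 2, n)
            if y.min() == y.max():
                y[0] = 1 - y[0]
            score = np.round(rng.normal(size=n), 1)  # induce ties
            auc, _, _ = delong_auc(y, score)
            assert auc == pytest.approx(bruteforce_auc(y, score), abs=1e-12)

    def test_independent_score_near_half(self, rng):
        n = 2000
        y = rng.integers(0, 2, n)
        auc, _, _ = delong_auc(y, rng.normal(size=n))
        assert auc == pytest.approx(0.5, abs=0.03)

    def test_constant_score_signalled(self):
        with pytest.raises(ValueError, match="constant"):
            delong_auc(np.array([0, 1, 0, 1]), np.ones(4))


class TestCompareAuc:
    def test_model_against_itself_p_one(self, rng):
        y = rng.integers(0, 2, 50)
        y[:2] = [0, 1]
        s = rng.normal(size=50)
        diff, p = compare_auc(y, s, s)
        assert diff == 0.0
        assert p == 1.0

    def test_tiny_identical_scores_not_significant(self, rng):
        y = np.array([0, 1] * 5)
        s = rng.normal(size=10)
        _, p = compare_auc(y, s, s + 1e-15)
        assert p > 0.9

    def test_informative_score_beats_noise(self, rng):
        n = 400
        y = rng.integers(0, 2, n)
        good = y + rng.normal(0, 0.5, n)
        noise = rng.normal(size=n)
        diff, p = compare_auc(y, good, noise)
        assert diff > 0
        assert p < 0.001


class TestMannWhitney:
    def test_identical_samples_symmetric(self):
        a = [1.0, 2.0, 3.0, 4.0]
        u, p = mann_whitney(a, a)
        assert u == len(a) ** 2 / 2
        assert p > 0.97

    def test_exact_small_sample_enumeration(self):
        # all 20 orderings of {1,2,3} vs {4,5,6}: U = 0 is one of 20 per tail
        u, p = mann_whitney([1, 2, 3], [4, 5, 6])
        assert u == 0.0
        assert p == pytest.approx(0.1, abs=1e-12)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney([], [1.0])

    def test_power_exceeds_type_one_at_ten_vs_ten(self, rng):
        """Shifted distributions are detected more often than alpha under
        the null, in the 10-vs-10 design."""
        rejections_null = 0
        rejections_shift = 0
        for _ in range(100):
            a = rng.normal(0, 1, 10)
            b_null = rng.normal(0, 1, 10)
            b_shift = rng.normal(1.8, 1, 10)
            rejections_null += mann_whitney(a, b_null)[1] < 0.05
            rejections_shift += mann_whitney(a, b_shift)[1] < 0.05
        assert rejections_null <= 12         # ~5% of 100
        assert rejections_shift >= 60        # high power at shift 1.8 SD
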