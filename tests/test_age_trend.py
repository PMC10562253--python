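"""Age-prevalence trends, weighted gradients and the deviation test."""

import numpy as np
import pytest
from scipy.optimize import minimize

from conftest import make_calls
from mosaicfit.age_trend import (
    AgePrevalencePoint,
    _assemble_trend,
    _point,
    build_age_trend,
    class_trend,
    deviation_test,
    expected_trend,
    fit_gradient,
    mca_detection_floor,
    observed_prevalence,
)
from mosaicfit.exceptions import InsufficientDataError, ValidationError
from mosaicfit.inference import FitOptions, MCACall, bootstrap_ci, fit_single
from mosaicfit.synthetic import (
    CohortSpec,
    GroundTruth,
    LabelTruth,
    sample_calls_theory,
    sample_spectrum_fractions,
)
from mosaicfit.theory import (
    AgeGroup,
    AgeMixture,
    DetectionWindow,
    TheoryParams,
    UKB_AGE_MIXTURE,
    expected_prevalence,
)

EQUAL_MIXTURE = AgeMixture(
    (AgeGroup(40, 50, 1 / 3), AgeGroup(50, 60, 1 / 3), AgeGroup(60, 70, 1 / 3))
)


def _call(pid, age, f=0.02, label="20q-"):
    return MCACall(pid, age, "female", label, "loss", f)


class TestObservedPrevalence:
    def test_direct_count_per_decade(self):
        cohort = CohortSpec(n_people=300, age_mixture=EQUAL_MIXTURE)
        calls = [_call(f"P{i}", 45.0) for i in range(10)]
        pts = observed_prevalence(calls, cohort, "20q-")
        assert [p.p for p in pts] == [0.10, 0.0, 0.0]
        assert pts[0].sd == pytest.approx(np.sqrt(0.1 * 0.9 / 100))

    def test_person_with_two_calls_counted_once(self):
        cohort = CohortSpec(n_people=300, age_mixture=EQUAL_MIXTURE)
        calls = [_call("P1", 45.0, 0.02), _call("P1", 45.0, 0.08)]
        pts = observed_prevalence(calls, cohort, "20q-")
        assert pts[0].k == 1

    def test_absent_label_gives_zero_points(self):
        cohort = CohortSpec(n_people=300, age_mixture=EQUAL_MIXTURE)
        pts = observed_prevalence([], cohort, "5q-")
        assert all(p.k == 0 for p in pts)

    def test_calls_below_floor_ignored(self):
        cohort = CohortSpec(n_people=300, age_mixture=EQUAL_MIXTURE)
        calls = [_call("P1", 45.0, 0.008), _call("P2", 45.0, 0.05)]
        pts = observed_prevalence(calls, cohort, "20q-", f_lo=0.01)
        assert pts[0].k == 1

    def test_simulated_cohort_matches_expectation_within_two_sd(self):
        truth = TheoryParams(s=0.12, ntau=1e5, mu=5e-8)
        cohort = CohortSpec(n_people=200_000)
        gt = GroundTruth((LabelTruth(label="20q-", mca_class="loss", s=0.12, mu=5e-8),))
        hits = 0
        for seed in range(6):
            calls = sample_calls_theory(gt, cohort, seed=seed)
            pts = observed_prevalence(calls, cohort, "20q-", f_lo=0.007)
            ok = True
            for g, p in zip(cohort.age_mixture.groups, pts):
                exp_p = expected_prevalence(truth, g.rep_age, DetectionWindow(0.007, 0.67))
                sd = max(p.sd, np.sqrt(exp_p / p.T))
                # allow 2 sd plus the small within-decade age-averaging offset
                if abs(p.p - exp_p) > 2 * sd + 0.05 * exp_p:
                    ok = False
            hits += ok
        assert hits >= 5


class TestGradient:
    def test_exact_line_recovered(self):
        pts = [_point(40, 50, 45, 1000, 45 * 2 + 100), _point(50, 60, 55, 1000, 55 * 2 + 100),
               _point(60, 70, 65, 1000, 65 * 2 + 100)]
        g = fit_gradient(pts)
        assert g.m == pytest.approx(2e-3, rel=1e-9)
        assert g.c == pytest.approx(0.1, rel=1e-9)

    def test_equal_weights_reduce_to_ols(self):
        # equal T and p -> constant weight -> plain least squares
        y = np.array([0.01, 0.013, 0.011])
        pts = [_point(40, 50, 45, 1000, 1000 * y[0]), _point(50, 60, 55, 1000, 1000 * y[1]),
               _point(60, 70, 65, 1000, 1000 * y[2])]
        g = fit_gradient(pts, weights=[1.0, 1.0, 1.0])
        m_ols, c_ols = np.polyfit([45, 55, 65], y, 1)
        assert g.m == pytest.approx(m_ols, rel=1e-9)
        assert g.c == pytest.approx(c_ols, rel=1e-9)

    def test_weighted_fit_matches_numerical_minimizer(self):
        # weights T/(2p) with unequal T change the answer; oracle = direct
        # numerical minimisation of the weighted L2 objective
        t = np.array([45.0, 55.0, 65.0])
        p = np.array([0.010, 0.018, 0.022])  # non-collinear
        T = np.array([5000.0, 800.0, 12000.0])
        pts = [_point(lo, lo + 10, ti, Ti, Ti * pi) for lo, ti, Ti, pi in zip((40, 50, 60), t, T, p)]
        g = fit_gradient(pts)
        w = T / (2 * p)

        def loss(mc):
            m, c = mc
            return np.sum(w * (p - (m * t + c)) ** 2)

        res = minimize(loss, x0=[1e-4, 0.0], method="Nelder-Mead",
                       options={"xatol": 1e-12, "fatol": 1e-18})
        assert g.m == pytest.approx(res.x[0], rel=1e-4)
        # and it differs from the equal-T solution
        g_equal = fit_gradient(pts, weights=[1 / (2 * pi) for pi in p])
        assert abs(g.m - g_equal.m) > 1e-6

    def test_single_usable_point_is_undetermined(self):
        pts = [_point(40, 50, 45, 1000, 10), _point(50, 60, 55, 1000, 0),
               _point(60, 70, 65, 1000, 0)]
        g = fit_gradient(pts)
        assert not g.determined


class TestExpectedAndClassTrend:
    @pytest.fixture
    def loss_fit(self, small_cohort):
        rng = np.random.default_rng(17)
        f = sample_spectrum_fractions(
            TheoryParams(s=0.13, ntau=1e5, mu=2e-8), UKB_AGE_MIXTURE,
            DetectionWindow(0.007, 0.67), 400, rng,
        )
        return fit_single(make_calls(f), small_cohort)

    def test_expected_trend_matches_prevalence_integral(self, loss_fit, small_cohort):
        window = DetectionWindow(0.007, 0.67)
        pts = expected_trend(loss_fit, small_cohort, window=window)
        params = TheoryParams.from_amplitude(loss_fit.s_hat, loss_fit.amplitude_hat, ntau=1e5)
        for g, p in zip(small_cohort.age_mixture.groups, pts):
            assert p.p == pytest.approx(expected_prevalence(params, g.rep_age, window), rel=1e-12)

    def test_zero_mutation_rate_gives_zero_expectation(self, small_cohort):
        from dataclasses import replace

        fit0 = None
        rng = np.random.default_rng(18)
        f = sample_spectrum_fractions(
            TheoryParams(s=0.13, ntau=1e5, mu=2e-8), UKB_AGE_MIXTURE,
            DetectionWindow(0.007, 0.67), 100, rng,
        )
        fit0 = replace(fit_single(make_calls(f), small_cohort), amplitude_hat=0.0, mu_hat=0.0)
        pts = expected_trend(fit0, small_cohort, window=DetectionWindow(0.007, 0.67))
        assert all(p.p == 0 for p in pts)

    def test_class_trend_single_fit_reduces_to_expected_trend(self, loss_fit, small_cohort):
        trend = class_trend([loss_fit], small_cohort)
        pts = expected_trend(loss_fit, small_cohort,
                             window=small_cohort.windows["loss"])
        for a, b in zip(trend.points_expected, pts):
            assert a.p == pytest.approx(b.p, rel=1e-12)

    def test_class_trend_sums_member_expectations(self, loss_fit, small_cohort):
        from dataclasses import replace

        fit2 = replace(loss_fit, label="9q-")
        trend = class_trend([loss_fit, fit2], small_cohort)
        single = expected_trend(loss_fit, small_cohort, window=small_cohort.windows["loss"])
        for a, b in zip(trend.points_expected, single):
            assert a.p == pytest.approx(2 * b.p, rel=1e-12)

    def test_class_trend_rejects_mixed_classes(self, loss_fit, small_cohort):
        from dataclasses import replace

        gain_fit = replace(loss_fit, label="12+", mca_class="gain")
        with pytest.raises(ValidationError):
            class_trend([loss_fit, gain_fit], small_cohort)
        with pytest.raises(InsufficientDataError):
            class_trend([], small_cohort)

    def test_expected_decade_points_nearly_collinear_in_linear_regime(self, small_cohort):
        # f_lim far below phi(45): successive decade expectations grow linearly
        params = TheoryParams(s=0.2, ntau=1e5, mu=2e-8)
        w = DetectionWindow(0.0008, 1.0)  # phi(45) = 0.405, f_lim << phi
        p = [expected_prevalence(params, t, w) for t in (45.0, 55.0, 65.0)]
        residual = abs(p[1] - 0.5 * (p[0] + p[2]))
        assert residual / p[1] < 0.05


class TestDetectionFloor:
    def test_floor_is_1p5_times_minimum(self):
        calls = make_calls([0.01, 0.02, 0.4])
        assert mca_detection_floor(calls) == pytest.approx(0.015)

    def test_empty_calls_raise(self):
        with pytest.raises(InsufficientDataError):
            mca_detection_floor([])


class TestDeviation:
    def test_zero_deviation_when_observed_equals_expected(self):
        pts = [_point(40, 50, 45, 10_000, 100), _point(50, 60, 55, 10_000, 200),
               _point(60, 70, 65, 10_000, 300)]
        trend = _assemble_trend("20q-", pts, pts)
        assert trend.deviation == pytest.approx(0.0, abs=1e-12)
        assert trend.m_obs == pytest.approx(trend.m_exp)

    def test_zero_observed_decade_excluded_from_both_gradients(self):
        obs = [_point(40, 50, 45, 10_000, 0), _point(50, 60, 55, 10_000, 200),
               _point(60, 70, 65, 10_000, 300)]
        exp = [_point(40, 50, 45, 10_000, 90), _point(50, 60, 55, 10_000, 210),
               _point(60, 70, 65, 10_000, 290)]
        trend = _assemble_trend("20q-", obs, exp)
        assert trend.excluded_groups == (0,)
        # expected gradient from the two remaining points only
        assert trend.m_exp == pytest.approx((0.029 - 0.021) / 10, rel=1e-9)

    def test_flat_observed_prevalence_detected_as_negative_deviation(self):
        # an mCA whose prevalence does not rise with age, against a rising
        # model expectation, must come out significantly negative for large T
        cohort = CohortSpec(n_people=400_000)
        gt = GroundTruth((LabelTruth(label="2q=", mca_class="cnloh", s=0.12, mu=8e-8),))
        calls = sample_calls_theory(gt, cohort, seed=42)
        fit = bootstrap_ci(calls, cohort, options=FitOptions(seed=0, bootstrap_B=80))
        trend = build_age_trend(fit, calls, cohort)
        T = [p.T for p in trend.points_observed]
        flat_p = trend.points_observed[1].p
        flat_obs = [_point(p.age_lo, p.age_hi, p.t, p.T, round(flat_p * p.T))
                    for p in trend.points_observed]
        flat_trend = _assemble_trend("2q=", flat_obs, list(trend.points_expected),
                                     window=trend.window)
        flat_trend = deviation_test(flat_trend, fit, cohort, seed=1)
        assert flat_trend.deviation < -0.5
        assert flat_trend.significant
        assert flat_trend.p_value < 0.05

    def test_undetermined_trend_reports_reason(self, small_cohort):
        obs = [_point(40, 50, 45, 10_000, 0), _point(50, 60, 55, 10_000, 0),
               _point(60, 70, 65, 10_000, 300)]
        exp = obs
        trend = _assemble_trend("20q-", obs, exp)
        rng = np.random.default_rng(3)
        f = sample_spectrum_fractions(
            TheoryParams(s=0.13, ntau=1e5, mu=2e-8), UKB_AGE_MIXTURE,
            DetectionWindow(0.007, 0.67), 100, rng,
        )
        fit = bootstrap_ci(make_calls(f), small_cohort, B=30)
        out = deviation_test(trend, fit, small_cohort)
        assert out.p_value is None
        assert out.p_value_reason == "undetermined gradient"
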