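"""Synthetic cohort generator and the forward branching-process oracle."""

import dataclasses

import numpy as np
import pytest
from scipy.integrate import quad
from scipy.stats import kstest

from mosaicfit.exceptions import ConfigurationError, DomainError, ValidationError
from mosaicfit.inference import fit_single
from mosaicfit.synthetic import (
    CohortSpec,
    ComponentTruth,
    GroundTruth,
    LabelTruth,
    _combine_fractions,
    _draw_fractions,
    apply_censoring,
    sample_calls_theory,
    simulate_allosome_interference,
    simulate_branching,
)
from mosaicfit.theory import (
    DetectionWindow,
    TheoryParams,
    detection_conditional_cdf,
    expected_prevalence,
)

LOSS = LabelTruth(label="20q-", mca_class="loss", s=0.15, mu=2e-8)


class TestCohortSpec:
    def test_sex_split_sums_to_total(self):
        c = CohortSpec(n_people=482_789)
        assert c.n_female + c.n_male == c.n_people
        assert c.n_female == 261_890

    def test_for_sex_restricts(self):
        c = CohortSpec(n_people=1000, sex_ratio=0.6)
        assert c.for_sex("female").n_people == 600
        assert c.for_sex("male").n_people == 400

    def test_invalid_specs_rejected(self):
        with pytest.raises(ConfigurationError):
            CohortSpec(n_people=0)
        with pytest.raises(ConfigurationError):
            CohortSpec(sex_ratio=1.2)


class TestTheorySampler:
    def test_zero_mutation_rate_yields_no_calls(self):
        truth = GroundTruth((LabelTruth(label="20q-", mca_class="loss", s=0.15, mu=0.0),))
        assert sample_calls_theory(truth, CohortSpec(n_people=10_000), seed=0) == []

    def test_total_count_matches_poisson_aggregation(self):
        cohort = CohortSpec(n_people=200_000)
        params = TheoryParams(s=LOSS.s, ntau=cohort.ntau, mu=LOSS.mu)
        w = cohort.windows["loss"]
        # exact mean: decade-uniform age averaging of the prevalence integral
        mean = sum(
            g.weight * quad(lambda t: expected_prevalence(params, t, w), g.lo, g.hi)[0] / 10.0
            for g in cohort.age_mixture.groups
        ) * cohort.n_people
        counts = [len(sample_calls_theory(GroundTruth((LOSS,)), cohort, seed=s)) for s in range(4)]
        for c in counts:
            assert abs(c - mean) < 3 * np.sqrt(mean)

    def test_sampled_fractions_follow_truncated_cdf(self):
        # inverse-CDF correctness at a fixed age via Kolmogorov-Smirnov
        params = TheoryParams(s=0.15, ntau=1e5, mu=2e-8)
        w = DetectionWindow(0.007, 0.67)
        passes = 0
        for seed in range(6):
            rng = np.random.default_rng(seed)
            f = _draw_fractions(rng, params.s, params.ntau, np.full(4000, 60.0), w)
            stat = kstest(f, lambda v: detection_conditional_cdf(v, params, 60.0, w)).statistic
            passes += stat < 1.628 / np.sqrt(4000)  # 1% critical value
        assert passes >= 5

    def test_call_count_scales_linearly_in_mu_and_cohort_size(self):
        base = CohortSpec(n_people=150_000)
        n1 = len(sample_calls_theory(GroundTruth((LOSS,)), base, seed=1))
        truth2 = GroundTruth((dataclasses.replace(LOSS, mu=2 * LOSS.mu),))
        n_mu2 = len(sample_calls_theory(truth2, base, seed=2))
        n_pop2 = len(
            sample_calls_theory(GroundTruth((LOSS,)), CohortSpec(n_people=300_000), seed=3)
        )
        for doubled in (n_mu2, n_pop2):
            assert abs(doubled - 2 * n1) < 4 * np.sqrt(2 * n1)

    def test_missing_window_is_configuration_error(self):
        cohort = CohortSpec(n_people=1000, windows={"gain": DetectionWindow(0.007, 1.0)})
        with pytest.raises(ConfigurationError):
            sample_calls_theory(GroundTruth((LOSS,)), cohort, seed=0)

    def test_sex_overrides_apply(self):
        truth = GroundTruth(
            (dataclasses.replace(LOSS, female=ComponentTruth(s=0.15, mu=8e-8),
                                 male=ComponentTruth(s=0.15, mu=0.0)),)
        )
        calls = sample_calls_theory(truth, CohortSpec(n_people=100_000), seed=4)
        assert len(calls) > 0
        assert all(c.sex == "female" for c in calls)

    def test_end_to_end_seed_determinism(self):
        cohort = CohortSpec(n_people=100_000)
        runs = []
        for _ in range(2):
            calls = sample_calls_theory(GroundTruth((LOSS,)), cohort, seed=9)
            fit = fit_single(calls, cohort)
            runs.append((calls, dataclasses.asdict(fit)))
        assert runs[0][0] == runs[1][0]
        assert runs[0][1] == runs[1][1]


class TestBranching:
    def test_identical_seeds_identical_outputs(self):
        a = simulate_branching(0.15, 1e-5, 1e4, 5.0, 60.0, seed=3)
        b = simulate_branching(0.15, 1e-5, 1e4, 5.0, 60.0, seed=3)
        np.testing.assert_array_equal(a, b)

    def test_desk_scale_guard(self):
        with pytest.raises(DomainError):
            simulate_branching(0.15, 1.0, 1e7, 5.0, 60.0, seed=0)

    def test_fast_mode_requires_positive_fitness(self):
        with pytest.raises(DomainError):
            simulate_branching(0.0, 1e-6, 1e4, 5.0, 10.0, seed=0)

    def test_neutral_exact_mode_preserves_mean_clone_size(self):
        # critical birth-death: E[size] of an initiated clone stays 1
        rng_total = 0
        sizes = []
        N, mu, tau, age = 5000.0, 4e-3, 2.0, 8.0
        fr = simulate_branching(0.0, mu, N, tau, age, seed=11, mode="exact")
        n_surviving = len(fr)
        x = fr / (1 - fr) * N  # back to cell counts
        m_expected_arrivals = N * mu * age
        mean_size_all = x.sum() / m_expected_arrivals  # extinct clones count as 0
        assert mean_size_all == pytest.approx(1.0, abs=0.35)
        assert n_surviving < m_expected_arrivals  # most neutral clones go extinct

    def test_exact_mode_with_selection_grows(self):
        fr = simulate_branching(0.25, 2e-3, 5000.0, 2.0, 12.0, seed=13, mode="exact")
        x = fr / (1 - fr) * 5000.0
        assert x.max() > 5  # expanded clones present

    def test_pooled_spectrum_matches_clone_size_density(self):
        # the central oracle property: forward simulation reproduces the
        # closed-form density within 2 sem per log-fraction bin
        s, age, N, tau, mu = 0.15, 60.0, 1e5, 1.0, 1e-7
        n_pop = 20_000
        fr = simulate_branching(s, mu * n_pop, N, tau, age, seed=7)
        w = DetectionWindow(0.007, 0.9)
        det = fr[(fr >= w.f_lo) & (fr <= w.f_hi)]
        edges = np.geomspace(w.f_lo, w.f_hi, 12)
        counts, _ = np.histogram(det, bins=edges)
        dl = np.log(edges[1] / edges[0])
        dens = counts / (n_pop * dl)
        sem = np.sqrt(counts) / (n_pop * dl)
        params = TheoryParams(s=s, ntau=N * tau, mu=mu)
        from mosaicfit.theory import clone_density_log

        pred = np.array([
            quad(lambda l: clone_density_log(l, params, age), np.log(a), np.log(b))[0] / dl
            for a, b in zip(edges[:-1], edges[1:])
        ])
        z = np.abs(dens - pred) / np.maximum(sem, 1e-12)
        assert np.all(z < 2.0)


class TestCensoring:
    def test_class_windows_applied(self):
        calls = [
            # CN-LOH above its 54% cut-off drops out; high-fraction gains stay
            _mk("a", "9p=", "cnloh", 0.60),
            _mk("b", "12+", "gain", 0.95),
            _mk("c", "20q-", "loss", 0.70),
            _mk("d", "20q-", "loss", 0.30),
        ]
        kept = apply_censoring(calls)
        assert [c.person_id for c in kept] == ["b", "d"]

    def test_censoring_then_fitting_with_matching_window_is_unbiased(self):
        cohort = CohortSpec(n_people=400_000)
        truth = GroundTruth((LabelTruth(label="20q-", mca_class="loss", s=0.18, mu=2e-8),))
        full = sample_calls_theory(truth, cohort, seed=6, full_window=True)
        censored = apply_censoring(full)
        assert len(censored) < len(full)  # some losses really drop out above 67%
        fit = fit_single(censored, cohort)  # loss window (0.007, 0.67)
        assert abs(fit.s_hat - 0.18) < 0.02

    def test_cumulative_objective_insensitive_to_upper_window_edge(self):
        # the predicted cumulative count below the cut-off does not involve
        # the upper edge, so upper truncation cannot bias the fit through
        # window misspecification -- censoring only costs information
        cohort = CohortSpec(n_people=400_000)
        truth = GroundTruth((LabelTruth(label="20q-", mca_class="loss", s=0.18, mu=2e-8),))
        censored = apply_censoring(sample_calls_theory(truth, cohort, seed=6, full_window=True))
        fit = fit_single(censored, cohort)
        fit_full = fit_single(censored, cohort, window=DetectionWindow(0.007, 1.0))
        assert fit_full.s_hat == pytest.approx(fit.s_hat, rel=1e-9)


def _mk(pid, label, klass, f):
    from mosaicfit.inference import MCACall

    sex = "male" if klass == "mloy" else "female"
    return MCACall(pid, 60.0, sex, label, klass, f, length_mb=50.0)


class TestInterference:
    def test_combination_arithmetic(self):
        assert _combine_fractions(np.array([0.10, 0.04]), "mloy_sum", 1.0) == pytest.approx(0.14)
        assert _combine_fractions(np.array([0.10, 0.04]), "mlox_difference", 1.0) == pytest.approx(0.06)
        assert _combine_fractions(np.array([0.9, 0.4]), "mloy_sum", 1.0) == 1.0

    def test_single_clone_per_person_identical_to_plain_sampler(self):
        truth = GroundTruth((LabelTruth(label="Y-", mca_class="mloy", s=0.13, mu=1e-8),))
        cohort = CohortSpec(n_people=50_000)
        plain = sample_calls_theory(truth, cohort, seed=2)
        combined = simulate_allosome_interference(truth, cohort, "mloy_sum", seed=2)
        assert sorted(plain, key=lambda c: c.person_id) == sorted(
            combined, key=lambda c: c.person_id
        )

    def test_interference_modifies_only_multi_clone_tail(self):
        truth = GroundTruth((LabelTruth(label="Y-", mca_class="mloy", s=0.13, mu=9e-7),))
        cohort = CohortSpec(n_people=150_000)
        plain = sample_calls_theory(truth, cohort, seed=3)
        summed = simulate_allosome_interference(truth, cohort, "mloy_sum", seed=3)
        # many carriers exist; only the (rare) multi-clone persons collapse
        assert 0 < len(summed) <= len(plain)
        f_plain = np.sort([c.cell_fraction for c in plain])
        f_sum = np.sort([c.cell_fraction for c in summed])
        # low-fraction spectrum essentially unchanged
        q25 = np.quantile(f_plain, 0.25)
        assert np.quantile(f_sum, 0.25) == pytest.approx(q25, rel=0.1)

    def test_unknown_mode_rejected(self):
        truth = GroundTruth((LabelTruth(label="Y-", mca_class="mloy", s=0.13, mu=1e-8),))
        with pytest.raises(ConfigurationError):
            simulate_allosome_interference(truth, CohortSpec(n_people=100), "bad_mode")
        with pytest.raises(ValidationError):
            simulate_allosome_interference(
                GroundTruth((LOSS,)), CohortSpec(n_people=100), "mloy_sum"
            )
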