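"""NHT fitting, reference ranges, microstructure, rank-sum and KS tests."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from humscan.thresholds import (
    DEFAULT_FREQUENCIES,
    ThresholdProfile,
    classify_thresholds,
    compute_reference_range,
    fit_nht,
    ks_two_sample,
    microstructure_summary,
    rank_sum_test,
    summarize_spf,
)


def profile(freqs, thresholds, pid="P01", ear="left", spf=None):
    return ThresholdProfile(
        participant_id=pid, ear=ear, frequencies=np.asarray(freqs, float),
        thresholds=np.asarray(thresholds, float), spf=spf,
    )


def cubic_profiles(coeffs, axis="log10", n=5):
    freqs = np.asarray(DEFAULT_FREQUENCIES)
    x = np.log10(freqs) if axis == "log10" else freqs
    t = np.polyval(coeffs, x)
    return [profile(freqs, t, pid=f"P{i:02d}") for i in range(n)]


class TestNhtFit:
    def test_points_on_a_cubic_have_zero_residuals(self):
        coeffs = [2.0, -3.0, 1.0, 40.0]
        profiles = cubic_profiles(coeffs)
        model = fit_nht(profiles, axis="log10")
        fitted = model.predict(profiles[0].frequencies)
        assert np.allclose(fitted, profiles[0].thresholds, atol=1e-8)

    def test_linear_axis_supported(self):
        coeffs = [1e-4, -0.02, -0.5, 90.0]
        profiles = cubic_profiles(coeffs, axis="linear")
        model = fit_nht(profiles, axis="linear")
        assert np.allclose(model.predict(profiles[0].frequencies),
                           profiles[0].thresholds, atol=1e-6)

    def test_too_few_distinct_frequencies_rejected(self):
        p = profile([20, 40, 80], [70, 60, 50])
        with pytest.raises(ValueError):
            fit_nht([p])

    def test_recovers_generator_base_curve(self):
        from humscan.synth import SyntheticCohortSpec, generate_cohort

        spec = SyntheticCohortSpec(
            n_participants=200, between_subject_sd=3.0, ripple_amplitude=0.0,
            measurement_noise_sd=2.0, seed=5,
        )
        profiles, truth = generate_cohort(spec)
        model = fit_nht(profiles)
        f = np.asarray(DEFAULT_FREQUENCIES)
        true_curve = np.polyval(truth.base_curve, np.log10(f))
        # noise-scaled tolerance: SE of the mean over 200 subjects
        tol = 3 * np.sqrt(3.0**2 + 2.0**2) / np.sqrt(200)
        assert np.max(np.abs(model.predict(f) - true_curve)) < 3 * tol


class TestReferenceRange:
    def test_zero_residuals_give_zero_width(self):
        profiles = cubic_profiles([2.0, -3.0, 1.0, 40.0])
        model = fit_nht(profiles)
        rr = compute_reference_range(model, profiles)
        assert rr.lower_offset == pytest.approx(0.0, abs=1e-8)
        assert rr.upper_offset == pytest.approx(0.0, abs=1e-8)
        assert rr.width == pytest.approx(0.0, abs=1e-8)

    def test_percentiles_interpolate_order_statistics(self):
        """Hand-computed oracle for residuals {-10, 0, +10}: the 2.5th/97.5th
        percentiles with linear interpolation are -9.5 and +9.5."""
        from humscan.thresholds import NhtModel, ReferenceRange

        model = NhtModel(coefficients=np.array([0.0, 0.0, 0.0, 0.0]),
                         fit_domain=(16.0, 125.0), axis="log10")
        profs = [profile([20, 40, 80], [-10.0, 0.0, 10.0])]
        rr = compute_reference_range(model, profs)
        assert rr.lower_offset == pytest.approx(-9.5)
        assert rr.upper_offset == pytest.approx(9.5)
        assert rr.width == pytest.approx(19.0)

    def test_translation_equivariance(self):
        from humscan.synth import SyntheticCohortSpec, generate_cohort

        profiles, _ = generate_cohort(SyntheticCohortSpec(n_participants=20, seed=3))
        model = fit_nht(profiles)
        rr = compute_reference_range(model, profiles)
        shifted = [
            profile(p.frequencies, p.thresholds + 7.0, pid=p.participant_id)
            for p in profiles
        ]
        model2 = fit_nht(shifted)
        rr2 = compute_reference_range(model2, shifted)
        assert rr2.lower_offset == pytest.approx(rr.lower_offset, abs=1e-8)
        assert rr2.upper_offset == pytest.approx(rr.upper_offset, abs=1e-8)


class TestClassification:
    def _model_rr(self):
        profiles = cubic_profiles([2.0, -3.0, 1.0, 40.0])
        model = fit_nht(profiles)
        from humscan.thresholds import ReferenceRange

        return model, ReferenceRange(lower_offset=-12.0, upper_offset=11.0)

    def test_thresholds_on_the_curve_are_within_rr_and_not_below_nht(self):
        model, rr = self._model_rr()
        freqs = np.asarray(DEFAULT_FREQUENCIES)
        profs = [profile(freqs, model.predict(freqs))]
        s = classify_thresholds(profs, model, rr)
        assert s.frac_within_rr == 1.0
        assert s.frac_below_nht == 0.0  # equality is not "lower"
        assert s.frac_above_nht == 1.0

    def test_point_below_lower_offset_counts_below_rr(self):
        model, rr = self._model_rr()
        freqs = np.asarray(DEFAULT_FREQUENCIES)
        t = model.predict(freqs)
        t[2] -= abs(rr.lower_offset) + 5.0
        s = classify_thresholds([profile(freqs, t)], model, rr)
        assert s.frac_below_rr == pytest.approx(1 / 6)
        assert s.frac_below_nht == pytest.approx(1 / 6)

    def test_fractions_partition_to_one(self):
        from humscan.synth import SyntheticCohortSpec, generate_cohort

        profiles, _ = generate_cohort(SyntheticCohortSpec(n_participants=30, seed=9))
        model = fit_nht(profiles)
        rr = compute_reference_range(model, profiles)
        s = classify_thresholds(profiles, model, rr)
        assert s.frac_below_rr + s.frac_within_rr + s.frac_above_rr == pytest.approx(1.0)
        assert s.frac_below_nht + s.frac_above_nht == pytest.approx(1.0)

    def test_rr_boundary_is_inclusive(self):
        model, rr = self._model_rr()
        freqs = np.asarray(DEFAULT_FREQUENCIES)
        t = model.predict(freqs) + rr.upper_offset  # exactly on the limit
        s = classify_thresholds([profile(freqs, t)], model, rr)
        assert s.frac_within_rr == 1.0


class TestMicrostructure:
    def test_flat_profile_has_zero_depth(self):
        s = microstructure_summary(profile([40, 42, 44], [60, 60, 60]))
        assert s.depth == 0.0

    def test_depth_and_extrema_positions(self):
        freqs = np.arange(42, 51).astype(float)  # 9 frequencies
        t = [62, 58, 55, 60, 66, 61, 57, 63, 64]
        s = microstructure_summary(profile(freqs, t, spf=46.0))
        assert s.depth == 11.0
        assert s.min_frequency == 44.0  # 3rd frequency
        assert s.max_frequency == 46.0  # 5th frequency
        assert s.max_offset_from_spf == 0.0
        assert s.min_offset_from_spf == -2.0

    def test_ties_resolve_to_lowest_frequency(self):
        s = microstructure_summary(profile([40, 44, 48], [70, 60, 70]))
        assert s.max_frequency == 40.0

    def test_no_spf_means_no_offsets(self):
        s = microstructure_summary(profile([40, 44], [70, 60]))
        assert s.max_offset_from_spf is None and s.min_offset_from_spf is None
        assert s.depth == 10.0

    def test_depth_recovers_injected_ripple(self):
        """Mean depth over a cohort ~ 2*amplitude plus noise inflation."""
        from humscan.synth import SyntheticCohortSpec, generate_cohort

        amp = 6.0
        # flat base curve so the ripple is the only structure
        spec = SyntheticCohortSpec(
            n_participants=150, design="spf_offsets", ripple_amplitude=amp,
            ripple_period=16.0, measurement_noise_sd=0.0,
            base_curve=np.array([0.0, 0.0, 0.0, 60.0]), seed=21,
        )
        profiles, truth = generate_cohort(spec)
        depths = np.array([microstructure_summary(p).depth for p in profiles])
        # closed-form oracle: extrema of the sinusoid on each sampled grid
        expected = np.array([
            np.ptp(truth.true_threshold(i, p.frequencies, spec))
            for i, p in enumerate(profiles)
        ])
        assert np.allclose(depths, expected, atol=1e-9)
        # the 9-point offset grid spans one full 16-Hz period; grid sampling
        # can miss the exact extrema, so mean depth is a bit under 2*amp
        assert 2 * amp * 0.8 < np.mean(depths) <= 2 * amp + 1e-9


def exact_ranksum_p(a, b):
    """Brute-force two-sided p: enumerate all rank assignments."""
    n1 = len(a)
    ranks = stats.rankdata(np.concatenate([a, b]))
    mean_w = n1 * (len(a) + len(b) + 1) / 2.0
    d_obs = abs(ranks[:n1].sum() - mean_w)
    ws = [
        sum(ranks[list(idx)])
        for idx in itertools.combinations(range(len(ranks)), n1)
    ]
    return np.mean([abs(w - mean_w) >= d_obs - 1e-9 for w in ws])


class TestRankSum:
    def test_identical_samples_give_z_zero_p_one(self):
        r = rank_sum_test([5.0, 5.0, 5.0], [5.0, 5.0])
        assert r.z_value == 0.0
        assert r.p_value == 1.0

    def test_small_sample_p_equals_exact_enumeration(self):
        a, b = [1.0, 2.0, 3.0], [2.5, 4.0, 5.0]
        r = rank_sum_test(a, b)
        assert r.p_value == pytest.approx(exact_ranksum_p(a, b))

    def test_all_small_sample_sizes_match_enumeration_oracle(self):
        rng = np.random.default_rng(42)
        for n1 in range(1, 10):
            for n2 in range(1, 11 - n1):
                a = rng.integers(0, 6, n1).astype(float)
                b = rng.integers(0, 6, n2).astype(float)
                r = rank_sum_test(a, b)
                # statistic: mid-ranks summed over sample a
                ranks = stats.rankdata(np.concatenate([a, b]))
                assert r.rank_sum == pytest.approx(ranks[:n1].sum())
                assert r.p_value == pytest.approx(exact_ranksum_p(a, b))

    def test_normal_approximation_matches_scipy_on_random_instances(self):
        rng = np.random.default_rng(7)
        for _ in range(200):
            n1, n2 = rng.integers(8, 40, 2)
            a = rng.normal(0, 1, n1)
            b = rng.normal(rng.uniform(-1, 1), 1, n2)
            r = rank_sum_test(a, b, method="normal")
            ref = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
            assert r.p_value == pytest.approx(ref.pvalue, rel=1e-10)

    def test_rank_sum_bounds_invariant(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            n1, n2 = rng.integers(1, 12, 2)
            r = rank_sum_test(rng.normal(size=n1), rng.normal(size=n2))
            assert n1 * (n1 + 1) / 2 <= r.rank_sum <= n1 * (n1 + 2 * n2 + 1) / 2
            assert r.rank_sum + r.rank_sum_b == pytest.approx(
                (n1 + n2) * (n1 + n2 + 1) / 2
            )


def ecdf_scan_d(a, b):
    """Brute-force KS oracle: max ECDF gap over all pooled sample points."""
    a, b = np.sort(a), np.sort(b)
    grid = np.concatenate([a, b])
    d = 0.0
    for x in grid:
        fa = np.searchsorted(a, x, side="right") / len(a)
        fb = np.searchsorted(b, x, side="right") / len(b)
        d = max(d, abs(fa - fb))
    return d


class TestKs:
    def test_identical_samples_give_zero_d(self):
        r = ks_two_sample([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert r.d_statistic == 0.0

    def test_disjoint_supports_give_d_one(self):
        r = ks_two_sample([1.0, 2.0, 3.0], [10.0, 20.0, 30.0])
        assert r.d_statistic == 1.0

    def test_matches_brute_force_ecdf_scan(self):
        rng = np.random.default_rng(11)
        for _ in range(200):
            n1, n2 = rng.integers(2, 25, 2)
            a = rng.normal(0, 1, n1)
            b = rng.normal(0.3, 1.2, n2)
            r = ks_two_sample(a, b)
            assert r.d_statistic == pytest.approx(ecdf_scan_d(a, b))
            assert 0.0 <= r.d_statistic <= 1.0


class TestSpfSummary:
    def test_single_value(self):
        assert summarize_spf([50.0]) == (50.0, [])

    def test_values_below_15hz_excluded(self):
        median, excluded = summarize_spf([10.0, 50.0])
        assert median == 50.0
        assert excluded == [10.0]

    def test_empty_after_exclusion_raises(self):
        with pytest.raises(ValueError):
            summarize_spf([5.0, 10.0])

    def test_profile_spf_below_15hz_rejected(self):
        with pytest.raises(ValueError):
            profile([40, 44], [60, 55], spf=10.0)
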