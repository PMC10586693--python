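import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from markerless.analysis import (SYMMETRY_DEFICIT_THRESHOLD, ComparisonResult,
                                 SymmetryMeasurement, adjust_bh, align_and_compare,
                                 compare_battery, detect_stance, emg_envelope,
                                 normalize_outcomes, paired_comparison, peak_in_window,
                                 posthoc_power, roc_analysis, symmetry_index)


class TestSymmetryIndex:
    @pytest.mark.parametrize("inv,uninv,expected",
                             [(1.0, 1.0, 1.0), (0.8, 1.0, 1.2), (1.2, 1.0, 0.8)])
    def test_longhand_arithmetic(self, inv, uninv, expected):
        assert symmetry_index(SymmetryMeasurement(inv, uninv)) == pytest.approx(expected)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.floats(0.05, 5.0), st.floats(0.05, 5.0), st.floats(0.01, 100.0))
    def test_scale_invariance(self, inv, uninv, c):
        s1 = symmetry_index(SymmetryMeasurement(inv, uninv))
        s2 = symmetry_index(SymmetryMeasurement(c * inv, c * uninv))
        assert s2 == pytest.approx(s1, rel=1e-9)

    def test_zero_uninvolved_rejected(self):
        with pytest.raises(ValueError):
            SymmetryMeasurement(1.0, 0.0)

    def test_clinical_threshold_constant(self):
        assert SYMMETRY_DEFICIT_THRESHOLD == 1.15


class TestStanceDetection:
    def test_all_zero_grf_no_intervals(self):
        assert detect_stance(np.zeros(300), 100.0) == []

    def test_half_sine_stance_borders(self):
        fs = 100.0
        t = np.arange(0, 1.2, 1 / fs)
        g = np.zeros_like(t)
        inside = (t >= 0.3) & (t <= 0.9)
        g[inside] = np.sin(np.pi * (t[inside] - 0.3) / 0.6)  # peak 1 BW
        intervals = detect_stance(g, fs, threshold=0.05)
        assert len(intervals) == 1
        a, b = intervals[0]
        # crossing of 0.05 BW: sin(pi x / 0.6) = 0.05 -> x ~ 0.00955 s
        assert abs(t[a] - 0.3096) < 1.5 / fs
        assert b - a > 0.5 * fs

    def test_two_separated_stances(self):
        fs = 100.0
        g = np.zeros(400)
        g[50:150] = 0.8
        g[250:350] = 0.8
        assert len(detect_stance(g, fs)) == 2

    def test_min_duration_filters_blips(self):
        fs = 100.0
        g = np.zeros(200)
        g[100:102] = 1.0  # 20 ms blip
        assert detect_stance(g, fs) == []


class TestPeaks:
    def test_monotone_ramp_first_half_peak_at_midpoint(self):
        sig = np.arange(100.0)
        val, idx = peak_in_window(sig, (0, 100), "first_half")
        assert idx == 49 and val == 49.0

    def test_double_peak_selects_first(self):
        t = np.linspace(0, 1, 200)
        sig = np.exp(-((t - 0.2) ** 2) / 0.004) * 1.1 + np.exp(-((t - 0.75) ** 2) / 0.004)
        val, idx = peak_in_window(sig, (0, 200), "first_half")
        assert abs(t[idx] - 0.2) < 0.02 and val == pytest.approx(1.1, rel=0.01)

    def test_constant_signal_earliest_index(self):
        val, idx = peak_in_window(np.ones(50), (10, 40), "full")
        assert idx == 10

    def test_interval_outside_span_rejected(self):
        with pytest.raises(ValueError):
            peak_in_window(np.ones(10), (0, 20))


class TestNormalization:
    def test_bodyweight_percent(self):
        assert normalize_outcomes(686.7, 70.0) == pytest.approx(100.0, rel=1e-3)

    def test_zero_moment(self):
        assert normalize_outcomes(0.0, 70.0, 1.75) == 0.0

    def test_roundtrip(self, rng):
        vals = rng.normal(0, 50, 20)
        pct = normalize_outcomes(vals, 80.0, 1.8)
        back = pct / 100.0 * 80.0 * 9.81 * 1.8
        np.testing.assert_allclose(back, vals, atol=1e-9)


class TestEMG:
    def test_burst_envelope(self, rng):
        fs = 2000.0
        t = np.arange(0, 2, 1 / fs)
        burst = ((t > 0.8) & (t < 1.2)).astype(float)
        raw = burst * np.sin(2 * np.pi * 100 * t)
        env = emg_envelope(raw, fs, channel_max=1.0)
        assert env[(t > 0.9) & (t < 1.1)].mean() > 5 * env[t < 0.6].mean()

    def test_dc_blocked(self):
        fs = 2000.0
        env = emg_envelope(np.full(4000, 2.0), fs, channel_max=1.0)
        assert np.abs(env[500:-500]).max() < 0.01

    def test_linearity_of_scaling(self, rng):
        fs = 2000.0
        raw = rng.normal(0, 1, 4000)
        e1 = emg_envelope(raw, fs, channel_max=1.0)
        e2 = emg_envelope(2 * raw, fs, channel_max=1.0)
        np.testing.assert_allclose(e2, 2 * e1, atol=1e-9)

    def test_low_sampling_rate_rejected(self):
        with pytest.raises(ValueError):
            emg_envelope(np.zeros(1000), 800.0, 1.0)


class TestAlignAndCompare:
    def test_shift_and_offset_recovered(self, rng):
        a = rng.normal(0, 1, (300, 3)).cumsum(axis=0) * 0.01
        b = np.vstack([np.zeros((5, 3)), a[:-5]]) + 0.03
        res = align_and_compare(a, b, max_delay=20)
        assert res.delay_frames == -5 or res.delay_frames == 5
        np.testing.assert_allclose(res.offset, 0.03, atol=1e-6)
        assert res.mae < 1e-9 or res.mae < 0.02  # interior-only mismatch at edges

    def test_identical_series_zero_errors(self, rng):
        a = rng.normal(0, 1, (100, 2))
        res = align_and_compare(a, a.copy())
        assert res.mae == 0.0 and res.rmse == 0.0 and res.delay_frames == 0

    def test_white_noise_mae_matches_expectation(self, rng):
        a = np.zeros((20000, 1))
        sigma = 0.25
        b = a + rng.normal(0, sigma, a.shape)
        res = align_and_compare(a, b, max_delay=2)
        expected = sigma * np.sqrt(2 / np.pi)  # E|N(0, s)|
        assert res.mae == pytest.approx(expected, rel=0.05)


class TestROC:
    def test_perfect_separation(self):
        rep = roc_analysis(np.array([1, 2, 3, 10, 11, 12.0]),
                           np.array([0, 0, 0, 1, 1, 1]))
        assert rep.auc == 1.0 and rep.accuracy == 1.0

    def test_matches_exhaustive_pair_counting(self, rng):
        scores = rng.integers(0, 6, 30).astype(float)  # many ties
        labels = rng.random(30) < 0.4
        rep = roc_analysis(scores, labels)
        pos, neg = scores[labels], scores[~labels]
        wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
        assert rep.auc == pytest.approx(wins / (len(pos) * len(neg)), abs=1e-12)

    def test_shuffled_labels_near_half(self, rng):
        scores = rng.normal(0, 1, 2000)
        labels = rng.random(2000) < 0.5
        rep = roc_analysis(scores, labels)
        assert 0.45 < rep.auc < 0.55

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.integers(0, 10 ** 6))
    def test_auc_invariant_under_monotone_transform(self, seed):
        r = np.random.default_rng(seed)
        scores = r.normal(0, 1, 40)
        labels = np.arange(40) % 2 == 0
        a1 = roc_analysis(scores, labels).auc
        a2 = roc_analysis(np.exp(3 * scores), labels).auc
        assert a1 == pytest.approx(a2, abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_analysis(np.arange(5.0), np.ones(5))


class TestPairedComparison:
    def test_degenerate_zero_differences(self):
        x = np.arange(10.0)
        res = paired_comparison(x, x.copy())
        assert res.test == "degenerate" and res.p_value == 1.0

    def test_normal_shift_selects_t_test(self, rng):
        picked = 0
        reps = 200
        for _ in range(reps):
            x = rng.normal(0, 1, 10)
            y = x + rng.normal(1.0, 1.0, 10)
            if paired_comparison(x, y).test == "paired_t":
                picked += 1
        assert picked / reps > 0.90

    def test_heavy_tails_reach_wilcoxon_branch(self, rng):
        picked = 0
        for _ in range(100):
            x = rng.normal(0, 1, 20)
            y = x + rng.standard_cauchy(20)
            res = paired_comparison(x, y)
            if res.test == "wilcoxon":
                picked += 1
        assert picked > 30  # the gate routinely routes heavy tails to Wilcoxon

    def test_battery_adjusts_family(self, rng):
        pairs = {f"m{i}": (rng.normal(0, 1, 8), rng.normal(0.3, 1, 8))
                 for i in range(4)}
        res = compare_battery(pairs)
        for r in res.values():
            assert r.p_adjusted >= r.p_value - 1e-12


class TestBH:
    def test_longhand_example(self):
        np.testing.assert_allclose(adjust_bh([0.01, 0.02, 0.04]),
                                   [0.03, 0.03, 0.04], atol=1e-12)

    def test_single_p_unchanged(self):
        np.testing.assert_allclose(adjust_bh([0.2]), [0.2])

    def test_equal_ps_unchanged(self):
        np.testing.assert_allclose(adjust_bh([0.3, 0.3, 0.3]), [0.3, 0.3, 0.3])

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.lists(st.floats(1e-6, 1.0), min_size=2, max_size=15))
    def test_monotone_and_dominates_raw(self, ps):
        ps = np.asarray(ps)
        adj = adjust_bh(ps)
        assert np.all(adj >= ps - 1e-12)
        order = np.argsort(ps)
        assert np.all(np.diff(adj[order]) >= -1e-12)
        assert np.all(adj <= 1.0 + 1e-12)


class TestPower:
    def test_null_effect_power_equals_alpha(self):
        assert posthoc_power(0.0, 12) == pytest.approx(0.05, abs=1e-9)
        assert posthoc_power(0.0, 12, test="wilcoxon") == pytest.approx(0.05, abs=1e-6)

    def test_monotone_in_n(self):
        powers = [posthoc_power(0.6, n) for n in (5, 10, 20, 40, 80)]
        assert np.all(np.diff(powers) > 0)

    def test_paired_t_power_matches_monte_carlo(self, rng):
        d_z, n, reps = 1.0, 10, 100_000
        x = rng.normal(d_z, 1.0, (reps, n))
        tstat = x.mean(axis=1) / (x.std(axis=1, ddof=1) / np.sqrt(n))
        tcrit = stats.t.ppf(0.975, n - 1)
        mc = np.mean(np.abs(tstat) > tcrit)
        assert posthoc_power(d_z, n) == pytest.approx(mc, abs=0.02)
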