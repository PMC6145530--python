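import itertools
import math

import numpy as np
import pytest
import scipy.signal
import scipy.stats
from hypothesis import given, settings
from hypothesis import strategies as st

from pencildec.rhythm import (
    ar_spectrum,
    arser_preprocess,
    arser_test,
    exact_null_pmf,
    scan_rhythm,
    trend_pvalue,
    trend_statistic,
)
from pencildec.timeseries import TimeSeries


def brute_force_pmf(sizes, variant, e=None):
    """Null pmf by exhaustive enumeration of all distinct rank arrangements."""
    from sympy.utilities.iterables import multiset_permutations

    labels = [g for g, m in enumerate(sizes) for _ in range(m)]
    counts: dict[int, int] = {}
    total = 0
    for perm in multiset_permutations(labels):
        groups = [[] for _ in sizes]
        for rank, g in enumerate(perm):
            groups[g].append(rank)  # rank = value (all distinct)
        s = trend_statistic(groups, variant, e)
        counts[s] = counts.get(s, 0) + 1
        total += 1
    smax = max(counts)
    return np.array([counts.get(i, 0) / total for i in range(smax + 1)])


class TestTrendStatistic:
    def test_monotone_increasing_singletons(self):
        assert trend_statistic([[1], [2], [3]], "jtk") == 3

    def test_monotone_decreasing_singletons(self):
        assert trend_statistic([[3], [2], [1]], "jtk") == 0

    def test_umbrella_matches_pair_counting(self):
        # [1],[3],[2] with peak e=2: rising (1<=3), falling (2<=3), wrap (1<=2)
        assert trend_statistic([[1], [3], [2]], "rain", e=2) == 3

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            trend_statistic([[1], []], "jtk")

    def test_midrank_ties(self):
        assert trend_statistic([[1], [1]], "jtk", midrank=True) == 0.5


class TestExactNull:
    @pytest.mark.parametrize("sizes, variant, e", [
        ((1, 1), "jtk", None),
        ((1, 1, 1), "jtk", None),
        ((2, 2), "jtk", None),
        ((1, 1, 1), "rain", 2),
        ((2, 1, 2), "rain", 2),
        ((1, 2, 2, 1), "rain", 3),
        ((2, 2, 2), "rain", 3),
    ])
    def test_matches_enumeration(self, sizes, variant, e):
        got = exact_null_pmf(sizes, variant, e)
        want = brute_force_pmf(sizes, variant, e)
        assert got.size == want.size
        assert np.allclose(got, want, atol=1e-12)

    def test_two_singletons_half_half(self):
        assert np.allclose(exact_null_pmf((1, 1), "jtk"), [0.5, 0.5])

    def test_three_singletons_uniform_extremes(self):
        pmf = exact_null_pmf((1, 1, 1), "jtk")
        assert pmf[-1] == pytest.approx(1 / 6)

    @settings(deadline=None, derandomize=True, max_examples=30)
    @given(st.lists(st.integers(1, 3), min_size=2, max_size=5))
    def test_sums_to_one_and_jtk_symmetric(self, sizes):
        if sum(sizes) > 10:
            return
        pmf = exact_null_pmf(tuple(sizes), "jtk")
        assert pmf.sum() == pytest.approx(1.0, abs=1e-12)
        assert np.allclose(pmf, pmf[::-1], atol=1e-12)

    def test_budget_enforced(self):
        with pytest.raises(ValueError, match="budget"):
            exact_null_pmf((31, 31), "jtk")

    def test_rain_peak_at_one_rejected(self):
        with pytest.raises(ValueError):
            exact_null_pmf((1, 1, 1), "rain", e=1)


class TestTrendPvalue:
    def test_maximum_statistic_three_singletons(self):
        pmf = exact_null_pmf((1, 1, 1), "jtk")
        assert trend_pvalue(3, pmf) == pytest.approx(1 / 6)

    def test_zero_statistic_full_tail(self):
        pmf = exact_null_pmf((2, 2), "jtk")
        assert trend_pvalue(0, pmf) == 1.0

    def test_two_sided_capped(self):
        pmf = exact_null_pmf((1, 1), "jtk")
        assert trend_pvalue(0, pmf, "two-sided") == 1.0

    def test_out_of_support_rejected(self):
        with pytest.raises(ValueError):
            trend_pvalue(99, exact_null_pmf((1, 1), "jtk"))


class TestScan:
    def test_clean_circadian_rhythm_detected(self):
        t = np.arange(48.0)
        ts = TimeSeries(np.cos(2 * np.pi * t / 24))
        assert scan_rhythm(ts, 24, "rain").p_value < 0.01
        assert scan_rhythm(ts, 24, "jtk").p_value < 0.01

    def test_monotone_data_peaks_at_boundary(self):
        # a purely rising record is best explained by a boundary peak index
        ts = TimeSeries(np.arange(24.0) + 0.01 * np.sin(np.arange(24.0)))
        res = scan_rhythm(ts, 12, "rain")
        assert res.peak_index in (2, 12)  # an edge of the scanned e grid
        assert res.p_value < 0.05

    def test_null_level_controlled(self):
        rejections = {"jtk": 0, "rain": 0}
        n_sim = 200
        for seed in range(n_sim):
            ts = TimeSeries(np.random.default_rng(seed).normal(size=48))
            for variant in rejections:
                if scan_rhythm(ts, 24, variant).p_value <= 0.05:
                    rejections[variant] += 1
        for variant, rej in rejections.items():
            assert rej / n_sim <= 0.10, variant

    def test_rain_beats_jtk_on_sawtooth(self):
        """Asymmetric waveform (18 h rise, 6 h fall): the umbrella test should
        dominate the monotone test in most replicates."""
        t = np.arange(48)
        phase = t % 24
        saw = np.where(phase < 18, phase / 18.0, (24 - phase) / 6.0)
        wins = 0
        n_sim = 100
        for seed in range(n_sim):
            noise = np.random.default_rng(seed).normal(0, 0.2, size=48)
            ts = TimeSeries(saw + noise)
            p_rain = scan_rhythm(ts, 24, "rain").p_value
            p_jtk = scan_rhythm(ts, 24, "jtk").p_value
            wins += p_rain <= p_jtk
        assert wins / n_sim >= 0.80

    def test_noninteger_fold_warns(self):
        ts = TimeSeries(np.random.default_rng(0).normal(size=50), dt=1.0)
        with pytest.warns(UserWarning, match="not an integer"):
            scan_rhythm(ts, 24.5, "jtk")

    def test_record_longer_than_budget_rejected(self):
        with pytest.raises(ValueError, match="budget"):
            scan_rhythm(TimeSeries(np.arange(100.0)), 24, "jtk")


class TestArserPreprocess:
    def test_line_maps_to_zero(self):
        t = np.arange(48.0)
        pre = arser_preprocess(TimeSeries(2.0 + 0.3 * t))
        assert np.max(np.abs(pre.values)) < 1e-10

    def test_constant_maps_to_zero(self):
        pre = arser_preprocess(TimeSeries(np.full(48, 3.0)))
        assert np.max(np.abs(pre.values)) < 1e-12

    def test_sinusoid_preserved_with_small_attenuation(self):
        t = np.arange(48.0)
        pre = arser_preprocess(TimeSeries(1.0 + 0.5 * t + np.cos(2 * np.pi * t / 24)))
        # 24 h component survives the order-4 smoother nearly unattenuated
        c = np.cos(2 * np.pi * t / 24)
        c = c - c.mean()
        gain = np.dot(pre.values, c) / np.dot(c, c)
        assert abs(gain - 1.0) < 0.05

    def test_long_window_shrunk_with_warning(self):
        with pytest.warns(UserWarning, match="window"):
            arser_preprocess(TimeSeries(np.random.default_rng(1).normal(size=12)),
                             window=99)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            arser_preprocess(TimeSeries(np.arange(8.0)))


class TestArSpectrum:
    def test_ar1_peak_at_zero_frequency(self):
        rng = np.random.default_rng(4)
        y = np.empty(500)
        y[0] = rng.normal()
        for i in range(1, 500):
            y[i] = 0.9 * y[i - 1] + rng.normal()
        omega, s = ar_spectrum(y, 1, "yule-walker")
        assert omega[np.argmax(s)] < 0.02

    @pytest.mark.parametrize("method", ["yule-walker", "mle", "burg"])
    def test_circadian_peak_located(self, method):
        t = np.arange(72.0)
        rng = np.random.default_rng(0)
        y = np.cos(2 * np.pi * t / 24) + 0.2 * rng.normal(size=72)
        with np.errstate(all="ignore"):
            omega, s = ar_spectrum(y, 24, method)
        # a local spectral peak sits at the circadian period (the pipeline
        # works with local maxima inside the search window, not the argmax)
        peak_periods = 2 * np.pi / omega[scipy.signal.find_peaks(s)[0]]
        assert np.any((peak_periods >= 23) & (peak_periods <= 25))

    def test_white_noise_flat_in_window(self):
        y = np.random.default_rng(11).normal(size=96)
        omega, s = ar_spectrum(y, 8, "yule-walker")
        window = (omega >= 2 * np.pi / 28) & (omega <= 2 * np.pi / 20)
        assert s[window].max() < 2 * np.median(s)

    def test_order_too_large_rejected(self):
        with pytest.raises(ValueError):
            ar_spectrum(np.arange(20.0), 10)


class TestArserTest:
    def test_high_snr_circadian_detection(self):
        t = np.arange(48.0)
        rng = np.random.default_rng(1)
        ts = TimeSeries(np.cos(2 * np.pi * t / 24) + 0.1 * rng.normal(size=48))
        res = arser_test(ts)
        assert res.p_value < 1e-6
        assert 23 <= res.periods[0] <= 25

    def test_noiseless_amplitude_recovered(self):
        t = np.arange(48.0)
        res = arser_test(TimeSeries(np.cos(2 * np.pi * t / 24)))
        assert res.amplitudes[0] == pytest.approx(1.0, abs=1e-2)

    def test_null_rejection_rate(self):
        ps = [arser_test(TimeSeries(
            np.random.default_rng(seed).normal(size=48))).p_value
            for seed in range(200)]
        rate = np.mean(np.array(ps) <= 0.05)
        assert 0.01 <= rate <= 0.12

    def test_null_pvalues_near_uniform(self):
        ps = np.array([arser_test(TimeSeries(
            np.random.default_rng(seed).normal(size=48))).p_value
            for seed in range(500)])
        assert scipy.stats.kstest(ps, "uniform").statistic < 0.1

    def test_no_fallback_gives_p_one_when_no_peak(self):
        # pure circadian record scanned in an ultradian window: no peak there
        y = np.cos(2 * np.pi * np.arange(48) / 24)
        res = arser_test(TimeSeries(y), search_window=(5.0, 7.0),
                         fallback_period=None)
        assert res.periods == () and res.p_value == 1.0
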