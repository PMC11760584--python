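"""TF-ST feature catalogue: oracle values, degenerate conventions, layout."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import inkpd
from inkpd.features import (
    COMMON_FEATURES,
    DEFAULT_CONFIG,
    extract_basic_stats,
    extract_channel,
    extract_difference,
    extract_distribution,
    extract_spectral,
    extract_temporal,
    extract_wavelet_mfcc,
    feature_catalogue,
)

FS = 200.0


class TestBasicStats:
    def test_exactly_fourteen_values(self):
        assert len(extract_basic_stats(np.arange(10.0))) == 14

    def test_one_to_hundred_closed_form(self):
        out = extract_basic_stats(np.arange(1.0, 101.0))
        assert out["mean"] == 50.5
        assert out["median"] == 50.5
        assert out["max"] == 100 and out["min"] == 1

    def test_constant_signal_degenerate_dispersion(self):
        out = extract_basic_stats(np.full(20, 3.5))
        assert out["max"] == out["min"] == out["mean"] == out["median"] == 3.5
        for k in ("standard_deviation", "variance", "interquartile_range",
                  "mean_absolute_deviation", "median_absolute_deviation"):
            assert out[k] == 0.0

    def test_empty_signal_rejected(self):
        with pytest.raises(ValueError):
            extract_basic_stats(np.array([]))


class TestDistribution:
    def test_symmetric_signal_zero_skewness(self):
        out = extract_distribution(np.array([-2.0, -1.0, 0.0, 1.0, 2.0]))
        assert out["skewness"] == pytest.approx(0.0, abs=1e-12)

    def test_histogram_counts_conserve_n(self):
        s = np.random.default_rng(0).normal(size=137)
        out = extract_distribution(s)
        assert sum(out[f"histogram_{k}"] for k in range(10)) == 137

    def test_zero_variance_kurtosis_skewness_zero(self):
        out = extract_distribution(np.full(10, 2.0))
        assert out["kurtosis"] == 0.0 and out["skewness"] == 0.0

    def test_ecdf_slope_on_uniform_grid(self):
        # values 0..100: P20 = 20, P80 = 80, slope = 0.6 / 60
        out = extract_distribution(np.arange(101.0))
        assert out["ecdf_slope"] == pytest.approx(0.6 / 60.0)


class TestTemporal:
    def test_zero_crossings_alternating(self):
        out = extract_temporal(np.array([1.0, -1.0, 1.0, -1.0]))
        assert out["zero_crossing_rate"] == 3

    @pytest.mark.parametrize("k", [3, 7])
    def test_sine_peak_count(self, k):
        t = np.linspace(0.0, k, k * 200, endpoint=False)
        out = extract_temporal(np.sin(2 * np.pi * t))
        assert out["number_of_peaks"] == k
        assert out["number_of_valleys"] == k

    def test_constant_signal_conventions(self):
        n = 25
        out = extract_temporal(np.full(n, 4.0))
        assert out["peak_to_peak_value"] == 0.0
        assert out["entropy"] == 0.0
        # path length of a flat signal: sum of sqrt(1 + 0) over N-1 steps
        assert out["signal_distance"] == n - 1
        assert out["peaks_values_mean"] == 0.0  # no peaks -> 0 by convention

    def test_auc_uses_time_axis(self):
        t = np.arange(11) / 10.0
        out = extract_temporal(np.ones(11), t)
        assert out["area_under_curve"] == pytest.approx(1.0)


class TestDifference:
    def test_hand_case(self):
        out = extract_difference(np.array([0.0, 1.0, 0.0]))
        assert out["diff_sum"] == 0.0
        assert out["sum_absolute_diff"] == 2.0

    def test_monotone_ramp_telescopes(self):
        n, h = 12, 0.5
        out = extract_difference(np.arange(n) * h)
        assert out["diff_sum"] == pytest.approx((n - 1) * h)
        assert out["sum_absolute_diff"] == pytest.approx((n - 1) * h)

    def test_constant_all_zero(self):
        out = extract_difference(np.full(9, 2.0))
        assert all(v == 0.0 for v in out.values())


class TestSpectral:
    def test_sine_peak_within_one_bin(self):
        n = int(4 * FS)
        t = np.arange(n) / FS
        out = extract_spectral(np.sin(2 * np.pi * 5.0 * t), FS)
        assert abs(out["maximum_peak_frequency"] - 5.0) <= FS / n
        assert abs(out["fundamental_frequency"] - 5.0) <= FS / n

    def test_constant_signal_degenerate(self):
        out = extract_spectral(np.full(64, 7.0), FS)
        assert out["maximum_power_spectrum"] == 0.0
        assert out["spectral_centroid"] >= 0.0

    @pytest.mark.parametrize("n", [16, 100, 1000])
    def test_fmc_length_fixed(self, n):
        out = extract_spectral(np.random.default_rng(1).normal(size=n), FS)
        assert sum(k.startswith("FMC_") for k in out) == DEFAULT_CONFIG.n_fmc


class TestWaveletMfcc:
    def test_constant_signal_near_zero_wavelet_mean(self):
        # long enough that boundary effects are a small fraction even at
        # the coarsest scale (mexh support ~16 * scale samples)
        out = extract_wavelet_mfcc(np.full(1024, 5.0), FS)
        for k in range(9):
            assert out[f"WAM_{k}"] < 0.1 * 5.0

    def test_energy_equals_variance_plus_mean_squared(self):
        s = np.sin(np.linspace(0, 20, 256)) * np.linspace(1, 3, 256)
        out = extract_wavelet_mfcc(s, FS)
        import pywt

        coef, _ = pywt.cwt(s, np.arange(1.0, 10.0), "mexh")
        for k in range(9):
            direct = float(np.mean(coef[k] ** 2))
            assert out[f"wavelet_energy_{k}"] == pytest.approx(direct)
            assert out[f"wavelet_energy_{k}"] == pytest.approx(
                out[f"wavelet_variance_{k}"] + np.mean(coef[k]) ** 2)

    def test_mfcc_length(self):
        out = extract_wavelet_mfcc(np.random.default_rng(0).normal(size=300), FS)
        assert sum(k.startswith("MFCC_") for k in out) == 12

    def test_short_signal_rejected(self):
        with pytest.raises(ValueError):
            extract_wavelet_mfcc(np.ones(8), FS)


class TestLayout:
    def test_layout_independent_of_content(self):
        rng = np.random.default_rng(0)
        a = extract_channel(rng.normal(size=64), FS)
        b = extract_channel(np.full(500, 2.0), FS)
        assert list(a) == list(b)

    def test_per_channel_count_matches_group_sum(self):
        # independent count oracle: sum of the documented group sizes
        expected = 14 + 15 + 27 + 6 + (DEFAULT_CONFIG.n_fmc + 6) + (9 * 4 + 1 + 12)
        assert len(feature_catalogue()) == expected
        assert len(extract_channel(np.random.default_rng(2).normal(size=64),
                                   FS)) == expected

    def test_common_set_is_fifteen_per_channel(self):
        out = extract_channel(np.random.default_rng(0).normal(size=64), FS,
                              feature_set="common")
        assert len(out) == 15
        assert tuple(out) == COMMON_FEATURES

    def test_extract_all_deterministic_and_tagged(self, one_sample):
        cs = inkpd.build_channelset(one_sample)
        v1 = inkpd.extract_all(cs, t=one_sample.time_seconds())
        v2 = inkpd.extract_all(cs, t=one_sample.time_seconds())
        np.testing.assert_array_equal(v1.values, v2.values)
        assert v1.names == v2.names
        assert set(v1.families) == {"kinematic", "pressure", "angle", "moment"}

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=10, deadline=None)
    def test_no_nan_for_random_finite_signals(self, seed):
        """No configuration of finite input may produce NaN/Inf features."""
        rng = np.random.default_rng(seed)
        kind = rng.integers(0, 4)
        n = int(rng.integers(20, 400))
        if kind == 0:
            s = np.full(n, float(rng.normal()))
        elif kind == 1:
            s = rng.normal(0, 10.0 ** rng.integers(-6, 9), size=n)
        elif kind == 2:
            s = np.zeros(n)
        else:
            s = rng.integers(0, 3, size=n).astype(float)
        out = extract_channel(s, FS)
        assert all(np.isfinite(v) for v in out.values())

    def test_scale_equivariance_spot_checks(self):
        rng = np.random.default_rng(5)
        s = rng.normal(size=200)
        a = extract_channel(s, FS)
        b = extract_channel(3.0 * s, FS)
        for k in ("max", "min", "mean", "standard_deviation"):
            assert b[k] == pytest.approx(3.0 * a[k], rel=1e-9)
        for k in ("number_of_peaks", "zero_crossing_rate", "number_of_changes"):
            assert b[k] == a[k]
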