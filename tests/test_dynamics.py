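"""Dynamic channel derivation: displacement, derivative chains, moment."""

import numpy as np
import pytest

from inkpd.dynamics import (
    ChannelConfig,
    FAMILY_SIZES,
    build_channelset,
    compute_displacement,
    compute_kinematics,
    compute_moment,
    compute_pressure_angle,
)


class TestDisplacement:
    def test_three_four_five_triangle(self, sample_factory):
        s = sample_factory([0, 3], [0, 4])
        np.testing.assert_allclose(compute_displacement(s), [0.0, 5.0])

    def test_single_point_is_zero(self, sample_factory):
        np.testing.assert_array_equal(compute_displacement(
            sample_factory([7], [9])), [0.0])

    def test_repeated_points_all_zero(self, sample_factory):
        s = sample_factory([2] * 6, [3] * 6)
        np.testing.assert_array_equal(compute_displacement(s), np.zeros(6))


class TestKinematics:
    def test_constant_position_gives_zero_derivatives(self, sample_factory):
        s = sample_factory([5] * 10, [5] * 10)
        k = compute_kinematics(s)
        for name in ("Velocity", "Acceleration", "Jerk",
                     "Velocity_h", "Acceleration_v", "Jerk_v"):
            np.testing.assert_array_equal(k[name], np.zeros(10))

    def test_fourteen_channels(self, sample_factory):
        k = compute_kinematics(sample_factory([0, 1, 2], [0, 0, 0]))
        assert len(k) == 14

    def test_uniform_motion_matches_finite_difference_oracle(self, sample_factory):
        v_true = 120.0  # units/s at fs = 200
        n = 50
        x = v_true * np.arange(n) / 200.0
        s = sample_factory(x, np.zeros(n))
        k = compute_kinematics(s)
        # independent forward-difference oracle
        oracle_v = np.diff(x) / (1 / 200.0)
        np.testing.assert_allclose(k["Velocity_h"][1:], oracle_v, rtol=1e-9)
        np.testing.assert_allclose(k["Velocity_h"][2:], v_true, rtol=1e-9)
        np.testing.assert_allclose(k["Acceleration_h"][2:], 0.0, atol=1e-9)

    def test_zero_dt_guard_never_divides_by_zero(self, sample_factory):
        s = sample_factory([0, 1, 2], [0, 0, 0])
        s.t = np.array([0.0, 0.0, 5.0])  # stuttered timestamp
        with pytest.warns(UserWarning, match="non-positive"):
            k = compute_kinematics(s)
        assert np.all(np.isfinite(k["Velocity"]))


class TestPressureAngle:
    def test_constant_pressure_zero_derivative(self, sample_factory):
        s = sample_factory([0] * 5, [0] * 5, pressure=[100] * 5)
        pa = compute_pressure_angle(s)
        np.testing.assert_array_equal(pa["Pressure_d"], np.zeros(5))

    def test_linear_ramp_constant_derivative(self, sample_factory):
        s = sample_factory([0] * 6, [0] * 6, pressure=np.arange(6) * 10.0)
        pa = compute_pressure_angle(s)
        np.testing.assert_allclose(pa["Pressure_d"][1:], 10.0 * 200.0)

    def test_single_sample_degenerate(self, sample_factory):
        pa = compute_pressure_angle(sample_factory([0], [0]))
        np.testing.assert_array_equal(pa["Pressure_d"], [0.0])

    def test_angles_keep_recorded_degrees(self, sample_factory):
        s = sample_factory([0, 1], [0, 1], tilt=[30, 40], azimuth=[120, 130])
        pa = compute_pressure_angle(s)
        np.testing.assert_array_equal(pa["Tilt"], [30, 40])
        np.testing.assert_array_equal(pa["Azimuth"], [120, 130])


class TestMoment:
    def test_hand_worked_case(self, sample_factory):
        # points (0,0),(4,0): centroid (2,0), r = 2 for both;
        # P=3, tilt 0deg, azimuth 90deg -> M = 3 * 1 * 2 * 1 = 6
        s = sample_factory([0, 4], [0, 0], pressure=[3, 3],
                           tilt=[0, 0], azimuth=[90, 90])
        np.testing.assert_allclose(compute_moment(s), [6.0, 6.0])

    def test_tilt_90_gives_zero(self, sample_factory):
        s = sample_factory([0, 4], [0, 2], pressure=[3, 5],
                           tilt=[90, 90], azimuth=[45, 70])
        np.testing.assert_allclose(compute_moment(s), 0.0, atol=1e-12)

    def test_azimuth_0_gives_zero(self, sample_factory):
        s = sample_factory([0, 4], [0, 2], pressure=[3, 5],
                           tilt=[10, 20], azimuth=[0, 0])
        np.testing.assert_allclose(compute_moment(s), 0.0, atol=1e-12)

    def test_centroid_point_gives_zero(self, sample_factory):
        s = sample_factory([0, 2, 4], [0, 0, 0], pressure=[3, 3, 3],
                           tilt=[0, 0, 0], azimuth=[90, 90, 90])
        assert compute_moment(s)[1] == 0.0

    def test_linear_in_pressure(self, sample_factory):
        rng = np.random.default_rng(0)
        p = rng.uniform(10, 100, 20)
        kwargs = dict(tilt=rng.uniform(0, 90, 20), azimuth=rng.uniform(0, 360, 20))
        x, y = rng.normal(size=20), rng.normal(size=20)
        m1 = compute_moment(sample_factory(x, y, pressure=p, **kwargs))
        m3 = compute_moment(sample_factory(x, y, pressure=3 * p, **kwargs))
        np.testing.assert_allclose(m3, 3 * m1, rtol=1e-12)


class TestChannelSet:
    def test_nineteen_channels_with_family_sizes(self, one_sample):
        cs = build_channelset(one_sample)
        assert len(cs.signals) == 19
        assert {f: len(cs.family(f)) for f in FAMILY_SIZES} == FAMILY_SIZES

    def test_moment_ablation_gives_eighteen(self, one_sample):
        cs = build_channelset(one_sample, ChannelConfig(include_moment=False))
        assert len(cs.signals) == 18
        assert cs.family("moment") == []

    def test_deterministic(self, one_sample):
        a = build_channelset(one_sample)
        b = build_channelset(one_sample)
        for name in a.signals:
            np.testing.assert_array_equal(a.signals[name], b.signals[name])

    def test_translation_invariance(self, sample_factory):
        """Shifting all coordinates leaves displacement chains and moment
        unchanged (the centroid shifts with the data)."""
        rng = np.random.default_rng(3)
        x, y = rng.normal(size=30) * 100, rng.normal(size=30) * 100
        p = rng.uniform(10, 100, 30)
        tilt, az = rng.uniform(0, 90, 30), rng.uniform(0, 360, 30)
        a = build_channelset(sample_factory(x, y, pressure=p, tilt=tilt, azimuth=az))
        b = build_channelset(sample_factory(x + 500, y - 300, pressure=p,
                                            tilt=tilt, azimuth=az))
        for name in ("Displacement", "Velocity", "Acceleration", "Jerk", "Moment"):
            np.testing.assert_allclose(b.signals[name], a.signals[name],
                                       rtol=1e-9, atol=1e-9, err_msg=name)

    def test_on_surface_restriction(self, sample_factory):
        s = sample_factory([0, 1, 2, 3], [0, 0, 0, 0], button=[1, 0, 0, 1])
        cs = build_channelset(s, ChannelConfig(on_surface_only=True))
        assert len(cs) == 2
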