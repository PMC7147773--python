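"""Kinematic primitives and outcome measures against closed-form oracles."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from svsbalance import (
    detect_foot_contacts,
    differentiate,
    gait_speed,
    lowpass_filter,
    measure_trial,
    min_com_bos_distance,
    select_stride_window,
    step_width_variability,
    step_widths,
    trunk_velocity_rms,
)
from svsbalance.errors import (
    InsufficientDistanceError,
    InsufficientStepsError,
    InvalidArgumentError,
    InvalidTaskError,
    SequenceError,
    TrialRejectedError,
)
from svsbalance.kinematics import FootContact, fill_gaps

from conftest import make_trial

RATE = 120.0


class TestLowpassFilter:
    def test_dc_gain_unity(self):
        out = lowpass_filter(np.full(600, 3.7), RATE)
        assert np.allclose(out, 3.7, atol=1e-9)

    def test_passband_gain_at_half_hertz(self):
        # oracle: analytic 4th-order Butterworth magnitude at 0.5/6 of cutoff
        # is 1/sqrt(1 + (0.5/6)^8) ~ 1; output amplitude must be within 1%
        t = np.arange(0, 10, 1 / RATE)
        x = np.sin(2 * math.pi * 0.5 * t)
        y = lowpass_filter(x, RATE)
        basis = np.column_stack([np.sin(2 * math.pi * 0.5 * t), np.cos(2 * math.pi * 0.5 * t)])
        amp = np.hypot(*np.linalg.lstsq(basis, y, rcond=None)[0])
        expected = 1.0 / math.sqrt(1.0 + (0.5 / 6.0) ** 8)
        assert amp == pytest.approx(expected, rel=0.01)

    def test_stopband_attenuation(self):
        t = np.arange(0, 10, 1 / RATE)
        y = lowpass_filter(np.sin(2 * math.pi * 30.0 * t), RATE)
        assert np.max(np.abs(y[120:-120])) < 0.05

    def test_zero_phase_on_symmetric_pulse(self):
        x = np.zeros(601)
        x[280:321] = 1.0 - np.abs(np.arange(-20, 21)) / 20.0  # triangular pulse
        y = lowpass_filter(x, RATE)
        assert np.argmax(y) == np.argmax(x)

    def test_short_series_rejected(self):
        with pytest.raises(InvalidArgumentError):
            lowpass_filter(np.zeros(8), RATE)


class TestDifferentiate:
    def test_affine_exact(self):
        t = np.arange(100) / RATE
        v = differentiate(0.8 * t + 2.0, RATE)
        assert np.allclose(v, 0.8, atol=1e-9)

    def test_constant_zero(self):
        assert np.allclose(differentiate(np.full(50, 1.3), RATE), 0.0)

    def test_quadratic_interior_exact(self):
        # central difference of a quadratic is exact; oracle = analytic a*t
        a = 2.0
        t = np.arange(200) / RATE
        v = differentiate(0.5 * a * t**2, RATE)
        assert np.allclose(v[1:-1], a * t[1:-1], atol=1e-6)

    def test_too_short(self):
        with pytest.raises(InvalidArgumentError):
            differentiate(np.array([1.0, 2.0]), RATE)


class TestTrunkVelocityRMS:
    def test_stationary_chest_zero(self, static_standing_trial):
        assert trunk_velocity_rms(static_standing_trial, "ML") < 1e-9

    def test_sinusoid_closed_form(self):
        # chest ML = A sin(2 pi f t): velocity RMS over whole cycles = 2 pi f A / sqrt(2)
        A, f = 0.02, 0.4
        t = np.arange(601) / RATE
        trial = make_trial(chest_z=A * np.sin(2 * math.pi * f * t))
        expected = 2 * math.pi * f * A / math.sqrt(2.0)
        assert trunk_velocity_rms(trial, "ML") == pytest.approx(expected, rel=0.02)

    def test_constant_velocity_ap(self):
        t = np.arange(601) / RATE
        trial = make_trial(chest_x=1.0 * t)
        rms = trunk_velocity_rms(trial, "AP", window=(60, 540))
        assert rms == pytest.approx(1.0, abs=1e-6)

    def test_empty_window_rejected(self, static_standing_trial):
        with pytest.raises(InvalidArgumentError):
            trunk_velocity_rms(static_standing_trial, "AP", window=(100, 100))


class TestMinComBosDistance:
    def test_static_separation(self, static_standing_trial):
        # toe_R is 0.16 m anterior of the chest in the static fixture
        assert min_com_bos_distance(static_standing_trial, "AP") == pytest.approx(
            0.16, abs=1e-6
        )

    def test_oscillating_chest_min_over_cycle(self):
        # chest oscillates +-0.05 around a point 0.20 behind toe_R -> min 0.15
        t = np.arange(601) / RATE
        trial = make_trial(chest_x=-0.04 + 0.05 * np.sin(2 * math.pi * 0.4 * t))
        assert min_com_bos_distance(trial, "AP") == pytest.approx(0.15, abs=2e-3)

    def test_chest_on_reference_gives_zero(self):
        trial = make_trial(chest_z=np.full(601, 0.085))  # fifthmet_R ML position
        assert min_com_bos_distance(trial, "ML") == pytest.approx(0.0, abs=1e-6)

    def test_walking_trial_rejected(self):
        with pytest.raises(InvalidTaskError):
            min_com_bos_distance(make_trial(task="walking"), "AP")


def _single_step_trial():
    """One swing-stance cycle of the right foot, sin^4 arc, 1 s swing."""
    rate = RATE
    t = np.arange(int(3 * rate) + 1) / rate
    y = np.zeros_like(t)
    sw = (t >= 1.0) & (t < 2.0)
    y[sw] = 0.05 * np.sin(math.pi * (t[sw] - 1.0)) ** 4
    midfoot_r = np.column_stack([np.full_like(t, 0.08), y + 0.03, np.full_like(t, 0.06)])
    return make_trial(task="walking", duration=3.0, overrides={"midfoot_R": midfoot_r})


class TestFootContacts:
    def test_single_step_detected_at_velocity_minimum(self):
        # oracle: brute-force minimum of the analytic swing velocity
        trial = _single_step_trial()
        contacts = detect_foot_contacts(trial, "right")
        assert len(contacts) == 1
        s = np.linspace(0, 1, 100001)
        v = np.gradient(0.05 * np.sin(math.pi * s) ** 4, s)
        expected_t = 1.0 + s[np.argmin(v)]
        assert contacts[0].time == pytest.approx(expected_t, abs=1.5 / RATE)

    def test_stationary_foot_no_contacts(self):
        trial = make_trial(task="walking")
        assert detect_foot_contacts(trial, "left") == []

    def test_bad_side_rejected(self):
        with pytest.raises(InvalidArgumentError):
            detect_foot_contacts(make_trial(task="walking"), "up")


def _contacts(frames_sides_ap):
    left, right = [], []
    for frame, side, ap in frames_sides_ap:
        c = FootContact(frame, frame / RATE, side, ap)
        (left if side == "left" else right).append(c)
    return left, right


class TestStrideWindow:
    def test_midpoint_selection_matches_brute_force(self):
        # 8 alternating contacts evenly spaced along 6 m
        records = [
            (int(i * 0.5 * RATE), "right" if i % 2 else "left", i * 0.75)
            for i in range(8)
        ]
        left, right = _contacts(records)
        window = select_stride_window(left, right, walkway_midpoint=3.0)
        merged = sorted(left + right, key=lambda c: c.frame_index)
        # oracle: exhaustive scan over candidate windows
        best = min(
            range(5),
            key=lambda i: abs(np.mean([c.ap_position for c in merged[i : i + 4]]) - 3.0),
        )
        assert window == merged[best : best + 4]
        assert [c.frame_index for c in window] == [c.frame_index for c in merged[2:6]]

    def test_exactly_four_contacts(self):
        left, right = _contacts(
            [(10, "left", 1.0), (70, "right", 1.7), (130, "left", 2.4), (190, "right", 3.1)]
        )
        assert len(select_stride_window(left, right, 3.0)) == 4

    def test_three_contacts_insufficient(self):
        left, right = _contacts([(10, "left", 1.0), (70, "right", 1.7), (130, "left", 2.4)])
        with pytest.raises(InsufficientStepsError):
            select_stride_window(left, right, 3.0)

    def test_non_alternating_rejected(self):
        left, right = _contacts(
            [(10, "left", 1.0), (70, "left", 1.7), (130, "right", 2.4), (190, "left", 3.1)]
        )
        with pytest.raises(SequenceError):
            select_stride_window(left, right, 3.0)


class TestStepWidths:
    def _parallel_track_trial(self, z_left=-0.05, z_right=0.05):
        n = 601
        t = np.arange(n) / RATE
        mf_l = np.column_stack([1.2 * t, np.full(n, 0.03), np.full(n, z_left)])
        mf_r = np.column_stack([1.2 * t + 0.3, np.full(n, 0.03), np.full(n, z_right)])
        return make_trial(
            task="walking", overrides={"midfoot_L": mf_l, "midfoot_R": mf_r}
        )

    def _window(self):
        return [
            FootContact(100, 100 / RATE, "left", 1.0),
            FootContact(160, 160 / RATE, "right", 1.9),
            FootContact(220, 220 / RATE, "left", 2.2),
            FootContact(280, 280 / RATE, "right", 3.1),
        ]

    def test_parallel_tracks(self):
        widths = step_widths(self._parallel_track_trial(), self._window())
        assert widths == pytest.approx([0.10, 0.10, 0.10], abs=1e-6)

    def test_midline_feet_zero_widths(self):
        widths = step_widths(self._parallel_track_trial(0.0, 0.0), self._window())
        assert widths == pytest.approx([0.0, 0.0, 0.0], abs=1e-9)

    def test_malformed_window(self):
        window = self._window()
        window[1] = FootContact(160, 160 / RATE, "left", 1.9)  # two lefts in a row
        with pytest.raises(SequenceError):
            step_widths(self._parallel_track_trial(), window)


class TestStepWidthVariability:
    def test_equal_widths_zero(self):
        assert step_width_variability([0.10, 0.10, 0.10]) == pytest.approx(0.0, abs=1e-15)

    def test_closed_form_sample_sd(self):
        assert step_width_variability([0.08, 0.10, 0.12]) == pytest.approx(0.02, abs=1e-12)

    @given(st.floats(-0.05, 0.05))
    @settings(max_examples=20, deadline=None)
    def test_translation_invariance(self, shift):
        base = [0.07, 0.11, 0.09]
        assert step_width_variability([w + shift for w in base]) == pytest.approx(
            step_width_variability(base), abs=1e-12
        )

    def test_wrong_count(self):
        with pytest.raises(InvalidArgumentError):
            step_width_variability([0.1, 0.1])


class TestGaitSpeed:
    def test_constant_speed(self):
        t = np.arange(int(6 * RATE)) / RATE
        trial = make_trial(task="walking", duration=6.0 - 1 / RATE, chest_x=1.2 * t)
        assert gait_speed(trial) == pytest.approx(1.2, abs=1e-6)

    def test_piecewise_speed_central_window(self):
        # excursion 0..6 m, 1.2 m/s inside the central 3 m, 1.0 m/s outside:
        # the measured speed is 3 m / 2.5 s regardless of the outer speeds
        rate = RATE
        xs, x = [], 0.0
        t = np.arange(int(7 * rate)) / rate
        for _ in t:
            xs.append(x)
            if x < 6.0:
                v = 1.2 if 1.5 <= x <= 4.5 else 1.0
                x = min(x + v / rate, 6.0)
        trial = make_trial(task="walking", duration=7.0 - 1 / rate, chest_x=np.array(xs))
        assert gait_speed(trial, distance=3.0) == pytest.approx(1.2, rel=0.01)

    def test_insufficient_excursion(self):
        t = np.arange(601) / RATE
        trial = make_trial(task="walking", chest_x=0.4 * t)  # 2 m total
        with pytest.raises(InsufficientDistanceError):
            gait_speed(trial)


class TestGapFill:
    def test_short_gap_interpolated(self):
        trial = make_trial()
        arr = trial.markers["chest"].copy()
        arr[100:105, 0] = np.nan
        trial.markers["chest"] = arr
        filled = fill_gaps(trial)
        assert not np.isnan(filled.markers["chest"]).any()
        assert filled.markers["chest"][102, 0] == pytest.approx(0.0, abs=1e-9)

    def test_long_gap_rejects_trial(self):
        trial = make_trial()
        arr = trial.markers["chest"].copy()
        arr[100:140, 0] = np.nan  # 0.33 s > 0.1 s limit
        trial.markers["chest"] = arr
        with pytest.raises(TrialRejectedError):
            fill_gaps(trial)


class TestInvariances:
    @given(st.floats(-2.0, 2.0), st.floats(-2.0, 2.0), st.floats(-2.0, 2.0))
    @settings(max_examples=10, deadline=None)
    def test_rigid_translation_invariance(self, dx, dy, dz):
        """Translating the whole marker set leaves every measure unchanged."""
        from svsbalance import CohortSpec, ThresholdProfile, simulate_standing_trial

        trial, _ = simulate_standing_trial(
            ThresholdProfile(1, 600, 300),
            ("standing", "challenged", "sham", "sinusoidal"),
            11,
            CohortSpec(),
        )
        m0 = measure_trial(trial)
        shifted = make_shifted(trial, np.array([dx, dy, dz]))
        m1 = measure_trial(shifted)
        assert m1.ml_trunk_velocity_rms == pytest.approx(m0.ml_trunk_velocity_rms, rel=1e-9)
        assert m1.ap_trunk_velocity_rms == pytest.approx(m0.ap_trunk_velocity_rms, rel=1e-9)
        assert m1.min_dist_com_ml_bos == pytest.approx(m0.min_dist_com_ml_bos, rel=1e-9)
        assert m1.min_dist_com_ap_bos == pytest.approx(m0.min_dist_com_ap_bos, rel=1e-9)

    @pytest.mark.parametrize("c", [0.5, 2.0])
    def test_unit_scaling(self, c):
        """Scaling positions by c scales RMS, distances, widths, SD and speed by c."""
        from svsbalance import CohortSpec, ThresholdProfile, simulate_walking_trial

        trial, _ = simulate_walking_trial(
            ThresholdProfile(1, 600, 300),
            ("walking", "unchallenged", "sham", "sinusoidal"),
            13,
            CohortSpec(),
        )
        m0 = measure_trial(trial)
        scaled = make_shifted(trial, np.zeros(3), scale=c)
        from svsbalance.kinematics import MeasurementParams

        params = MeasurementParams(
            walkway_midpoint_m=3.0 * c, gait_distance_m=3.0 * c
        )
        m1 = measure_trial(scaled, params)
        assert m1.ap_trunk_velocity_rms == pytest.approx(c * m0.ap_trunk_velocity_rms, rel=1e-6)
        assert m1.ml_trunk_velocity_rms == pytest.approx(c * m0.ml_trunk_velocity_rms, rel=1e-6)
        assert m1.gait_speed == pytest.approx(c * m0.gait_speed, rel=1e-6)
        assert m1.step_width_sd == pytest.approx(c * m0.step_width_sd, rel=1e-6)


def make_shifted(trial, offset, scale=1.0):
    from dataclasses import replace

    markers = {k: scale * v + offset for k, v in trial.markers.items()}
    return replace(trial, markers=markers)


class TestMeasureTrial:
    def test_walking_trial_fields_populated(self):
        from svsbalance import CohortSpec, ThresholdProfile, simulate_walking_trial

        trial, _ = simulate_walking_trial(
            ThresholdProfile(1, 600, 300),
            ("walking", "challenged", "svs", "cutaneous"),
            5,
            CohortSpec(),
        )
        tm = measure_trial(trial)
        assert len(tm.step_widths) == 3
        assert tm.step_width_sd >= 0.0
        assert tm.gait_speed > 0.0
        assert tm.min_dist_com_ap_bos is None
        assert tm.audit == ("fill_gaps", "lowpass_filter", "differentiate", "measure")

    def test_measures_byte_stable_regression(self):
        """Frozen-seed trial reproduces the same measures on every run."""
        from svsbalance import (
            CohortSpec,
            ThresholdProfile,
            simulate_standing_trial,
            simulate_walking_trial,
        )

        prof = ThresholdProfile(1, 600, 300)
        spec = CohortSpec()
        trial, _ = simulate_standing_trial(
            prof, ("standing", "challenged", "sham", "sinusoidal"), 42, spec
        )
        tm = measure_trial(trial)
        assert tm.ml_trunk_velocity_rms == pytest.approx(0.027240366430554545, abs=1e-15)
        assert tm.ap_trunk_velocity_rms == pytest.approx(0.03917199511555838, abs=1e-15)
        assert tm.min_dist_com_ml_bos == pytest.approx(0.13493830045800567, abs=1e-15)
        trialw, _ = simulate_walking_trial(
            prof, ("walking", "unchallenged", "svs", "cutaneous"), 42, spec
        )
        tmw = measure_trial(trialw)
        assert tmw.gait_speed == pytest.approx(1.3415938246548789, abs=1e-12)
        assert tmw.step_width_sd == pytest.approx(0.013746703082392479, abs=1e-15)
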