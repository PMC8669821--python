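"""Detector behaviour on constructed and generated signals."""

import numpy as np
import pytest

import mobifof as m
from mobifof import detect
from mobifof.core import G, IMURecording
from mobifof.simulate import _SignalCanvas, _tilt_rotation, default_phenotype


def _static_recording(tilt_deg=0.0, fs=100.0, duration=10.0, seed=0, noise=0.0):
    rng = np.random.default_rng(seed)
    canvas = _SignalCanvas(duration, fs)
    return canvas.to_recording(rng, fs, noise, noise, tilt_deg), rng


def _canvas_recording(duration, fs=100.0, noise=0.0, tilt=0.0, seed=0, build=None):
    rng = np.random.default_rng(seed)
    canvas = _SignalCanvas(duration, fs)
    if build:
        build(canvas)
    return canvas.to_recording(rng, fs, noise, noise, tilt)


class TestVerticalAxis:
    def test_upright_static_recovered(self):
        rec, _ = _static_recording(tilt_deg=0.0)
        v = detect.estimate_vertical_axis(rec)
        angle = np.degrees(np.arccos(np.clip(v[rec.axis("vertical")], -1, 1)))
        assert angle < 0.5

    def test_tilted_recovered_within_one_degree(self):
        rng = np.random.default_rng(3)
        rot = _tilt_rotation(8.0, rng)
        true_v = rot @ np.array([0.0, 0.0, 1.0])
        acc = np.tile(true_v * G, (1000, 1)) + rng.normal(0, 0.04, (1000, 3))
        rec = IMURecording(sample_rate=100.0, acc=acc, gyro=np.zeros((1000, 3)))
        v = detect.estimate_vertical_axis(rec)
        assert np.degrees(np.arccos(np.clip(v @ true_v, -1, 1))) < 1.0

    def test_zero_accelerometer_raises(self):
        rec = IMURecording(sample_rate=100.0, acc=np.zeros((1000, 3)),
                           gyro=np.zeros((1000, 3)))
        with pytest.raises(detect.NoGravityError):
            detect.estimate_vertical_axis(rec)

    def test_too_short_recording_raises(self):
        rec = IMURecording(sample_rate=100.0, acc=np.zeros((100, 3)),
                           gyro=np.zeros((100, 3)))
        with pytest.raises(ValueError):
            detect.estimate_vertical_axis(rec)


class TestBoutFilters:
    def test_speed_gate_and_min_duration_compose(self):
        # 25 s bout whose middle 12 s are at 0.1 m/s: both fragments < 15 s
        v = np.concatenate([np.full(7, 1.0), np.full(12, 0.1), np.full(6, 1.0)])
        assert detect.apply_bout_filters(v) == []

    def test_boundary_speed_exactly_gate_is_kept(self):
        v = np.full(20, 0.2)
        kept = detect.apply_bout_filters(v)
        assert len(kept) == 1 and len(kept[0][1]) == 20

    def test_idempotence(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            v = rng.uniform(0.0, 1.5, rng.integers(5, 120))
            once = detect.apply_bout_filters(v)
            for off, run in once:
                again = detect.apply_bout_filters(run)
                assert len(again) == 1
                assert again[0][0] == 0
                np.testing.assert_array_equal(again[0][1], run)

    def test_nan_speeds_excluded(self):
        v = np.full(40, 1.0)
        v[20] = np.nan
        kept = detect.apply_bout_filters(v)
        assert [len(r) for _, r in kept] == [20, 19]


class TestWalkingBouts:
    def test_single_bout_recovered(self):
        spec = default_phenotype("FOF-")
        rng = np.random.default_rng(0)

        def build(c):
            c.add_gait(30.0, 20.0, np.full(20, 1.0), spec.height)

        rec = _canvas_recording(80.0, noise=0.04, tilt=3.0, build=build)
        bouts = detect.detect_walking_bouts(rec, height=spec.height)
        assert len(bouts) == 1
        assert abs(bouts[0].duration - 20.0) <= 2.0
        assert abs(bouts[0].start - 30.0) <= 2.0

    def test_static_recording_empty(self):
        rec, _ = _static_recording(duration=60.0, noise=0.04)
        assert detect.detect_walking_bouts(rec) == []

    def test_short_recording_empty(self):
        rec, _ = _static_recording(duration=10.0)
        assert detect.detect_walking_bouts(rec) == []

    def test_speed_recovery_within_15_percent(self, short_days):
        spec, days = short_days
        rel = []
        for rec, tl in days:
            frame = detect.resolve_frame(rec)
            bouts = detect.detect_walking_bouts(rec, height=spec.height, frame=frame)
            from mobifof.validate import match_events
            for t, d in match_events(tl.walking_bouts, bouts):
                rel.append(np.nanmean(d.per_second_speed)
                           / np.mean(t.per_second_speed) - 1)
        assert rel and np.max(np.abs(rel)) < 0.15

    def test_monotonic_speed_ramp_preserved(self):
        spec = default_phenotype("FOF-")
        true_v = np.linspace(0.5, 1.3, 30)

        def build(c):
            c.add_gait(10.0, 30.0, true_v, spec.height)

        rec = _canvas_recording(50.0, noise=0.02, build=build)
        est = detect.estimate_instantaneous_speed(rec, 10.0, 40.0,
                                                  height=spec.height)
        ok = ~np.isnan(est)
        from scipy.stats import spearmanr
        rho = spearmanr(np.arange(30)[ok], est[ok]).statistic
        assert rho > 0.9

    def test_zero_vertical_excursion_gives_zero_speed(self):
        # AP steps present but no vertical displacement -> step length 0
        def build(c):
            t = np.arange(int(20 * c.fs)) / c.fs
            i0 = int(10 * c.fs)
            c.acc[i0:i0 + len(t), 0] += 1.0 * np.sin(2 * np.pi * 1.8 * t)

        rec = _canvas_recording(40.0, noise=0.0, build=build)
        est = detect.estimate_instantaneous_speed(rec, 10.0, 30.0)
        assert np.nanmax(est) < 0.05


class TestPosturalTransitions:
    def test_five_sts_block_detected_in_order(self, lab_session, fofneg_spec):
        rec, tl = lab_session
        seg = rec.slice(*rec.markers["sts_normal"])
        trans = detect.detect_postural_transitions(seg, fofneg_spec.body_mass)
        kinds = [t.kind for t in trans]
        assert kinds.count("sit_to_stand") == 5
        assert kinds.count("stand_to_sit") >= 4
        # alternating order
        assert kinds[:2] == ["sit_to_stand", "stand_to_sit"]

    def test_peak_power_within_20_percent(self, short_days):
        spec, days = short_days
        from mobifof.validate import match_events
        rel = []
        for rec, tl in days:
            trans = [t for t in detect.detect_postural_transitions(
                rec, spec.body_mass) if t.kind == "sit_to_stand"]
            for t, d in match_events(tl.sit_to_stands, trans):
                rel.append(d.peak_power / t.peak_power - 1)
        assert rel and np.max(np.abs(rel)) < 0.20

    def test_gait_only_recording_has_no_transitions(self):
        spec = default_phenotype("FOF-")

        def build(c):
            c.add_gait(10.0, 30.0, np.full(30, 1.0), spec.height)

        rec = _canvas_recording(50.0, noise=0.04, build=build)
        assert detect.detect_postural_transitions(rec, 80.0) == []

    def test_missing_body_mass_rejected(self, lab_session):
        rec, _ = lab_session
        with pytest.raises(ValueError):
            detect.detect_postural_transitions(rec, 0.0)


class TestTurns:
    def test_90_degree_turn_recovered(self):
        def build(c):
            c.add_turn(10.0, 2.0, 90.0)  # peak omega 90 deg/s

        rec = _canvas_recording(25.0, noise=0.04, tilt=4.0, build=build)
        turns = detect.detect_turns(rec)
        assert len(turns) == 1
        assert turns[0].peak_omega == pytest.approx(90.0, rel=0.10)
        assert turns[0].angle == pytest.approx(90.0, abs=8.0)

    def test_small_heading_correction_ignored(self):
        def build(c):
            c.add_turn(10.0, 1.5, 30.0)

        rec = _canvas_recording(25.0, build=build)
        assert detect.detect_turns(rec) == []

    def test_slow_long_turn_excluded_by_duration_cap(self):
        def build(c):
            c.add_turn(5.0, 12.0, 180.0)  # 12 s > 10 s cap

        rec = _canvas_recording(25.0, build=build)
        assert detect.detect_turns(rec) == []

    def test_mirroring_vertical_gyro_negates_angles_only(self, short_days):
        spec, days = short_days
        rec, _ = days[0]
        turns = detect.detect_turns(rec)
        mirrored = IMURecording(sample_rate=rec.sample_rate, acc=rec.acc,
                                gyro=-rec.gyro,
                                axis_convention=rec.axis_convention)
        mturns = detect.detect_turns(mirrored)
        assert len(turns) == len(mturns) > 0
        for a, b in zip(turns, mturns):
            assert a.angle == pytest.approx(-b.angle, abs=1e-6)
            assert a.peak_omega == pytest.approx(b.peak_omega, abs=1e-6)


class TestDetectionRecovery:
    def test_sensitivity_and_precision_on_synthetic_days(self, short_days):
        from mobifof.validate import RecoveryStats, evaluate_day

        spec, days = short_days
        stats = {"bouts": RecoveryStats(), "turns": RecoveryStats(),
                 "sists": RecoveryStats()}
        for rec, tl in days:
            evaluate_day(rec, tl, body_mass=spec.body_mass,
                         height=spec.height, stats=stats)
        for name, s in stats.items():
            assert s.sensitivity >= 0.9, name
            assert s.precision >= 0.9, name
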