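"""Trial pipeline: event detection, cycle analysis, comparisons, sweeps."""

import math
from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from treadgait.biped_model import GRAVITY, build_model
from treadgait.experiments import (
    CYCLE_POINTS,
    ComparisonResult,
    InsufficientCycles,
    TrialConfig,
    TrialResult,
    compare_kinematics,
    cycle_normalize,
    detect_fall,
    detect_gait_events,
    extract_grf,
    run_sweep,
    run_trial,
)
from treadgait.config import load_config, save_config
from treadgait.treadmill import TreadmillSpec


def fake_trial(mean_curves, fell=False, retained=5, grf=None, t=None,
               events=None):
    """Minimal TrialResult for analysis-stage unit tests."""
    n = 100 if t is None else len(t)
    return TrialResult(
        config=TrialConfig(), reference=None,
        t=np.arange(n) * 1e-2 if t is None else t,
        q=np.zeros((n, 9)), qd=np.zeros((n, 9)),
        grf=np.zeros((n, 4, 2)) if grf is None else grf,
        belt_speed=np.zeros(n), belt_force=np.zeros(n),
        events=np.array([]) if events is None else events,
        cycles={}, mean_curves=mean_curves,
        fell=fell, fall_time=None, mean_reward=1.0, retained_cycles=retained,
    )


class TestEventDetection:
    def test_square_wave_rising_edges(self):
        dt = 1e-3
        t = np.arange(0, 5.5, dt)
        grf = np.where((t % 1.1) < 0.66, 500.0, 0.0)  # 60% duty, period 1.1
        events = detect_gait_events(grf, dt, threshold=20.0)
        expected = np.arange(0, 5.5, 1.1)[1:]  # first rising edge at t=1.1
        assert len(events) == len(expected)
        assert np.all(np.abs(events - expected) <= dt + 1e-12)

    def test_all_zero_series_gives_empty_list(self):
        assert len(detect_gait_events(np.zeros(1000), 1e-3)) == 0

    def test_chatter_within_debounce_single_event(self):
        dt = 1e-3
        grf = np.zeros(1000)
        grf[100:105] = 30.0
        grf[110:115] = 30.0  # re-crossing 10 ms later
        grf[120:400] = 30.0
        events = detect_gait_events(grf, dt, threshold=20.0, debounce=0.1)
        assert len(events) == 1

    def test_min_unloaded_rejects_mid_stance_blip(self):
        dt = 1e-3
        grf = np.full(2000, 500.0)
        grf[500:520] = 0.0  # brief unload, then re-load at i=520
        events = detect_gait_events(grf, dt, threshold=20.0, debounce=0.1,
                                    min_unloaded=0.1)
        assert len(events) == 0

    def test_invalid_threshold(self):
        with pytest.raises(ValueError):
            detect_gait_events(np.zeros(10), 1e-3, threshold=0.0)


class TestCycleNormalize:
    def test_pure_sinusoid_maps_to_unit_cycle(self):
        dt, T = 1e-3, 1.1
        t = np.arange(0, 5 * T, dt)
        series = np.sin(2 * np.pi * t / T)
        events = np.array([T, 2 * T, 3 * T, 4 * T])
        cycles, mean = cycle_normalize(t, series, events)
        p = np.linspace(0.0, 1.0, CYCLE_POINTS)
        assert cycles.shape == (3, CYCLE_POINTS)
        assert np.allclose(mean, np.sin(2 * np.pi * p), atol=1e-4)

    def test_identical_cycles_mean_equals_each(self):
        t = np.arange(0, 4.0, 1e-3)
        series = np.cos(2 * np.pi * t)
        cycles, mean = cycle_normalize(t, series, np.array([1.0, 2.0, 3.0]))
        assert np.allclose(mean, cycles[0], atol=1e-9)

    def test_three_point_resampling_of_ramp(self):
        t = np.arange(0, 2.0, 1e-3)
        series = t.copy()  # linear ramp
        cycles, _ = cycle_normalize(t, series, np.array([0.5, 1.5]), n=3)
        assert np.allclose(cycles[0], [0.5, 1.0, 1.5], atol=1e-9)

    def test_insufficient_events(self):
        with pytest.raises(InsufficientCycles):
            cycle_normalize(np.arange(10.0), np.zeros(10), np.array([1.0]))


class TestCompareKinematics:
    def test_identical_curves_zero_differences(self):
        p = np.linspace(0, 1, CYCLE_POINTS)
        curves = {j: np.sin(2 * np.pi * p) * 10 for j in ("hip", "knee", "ankle")}
        c = compare_kinematics(fake_trial(dict(curves)), fake_trial(dict(curves)))
        assert all(v == 0.0 for v in c.max_diff_deg.values())
        assert all(v == 0.0 for v in c.rms_diff_deg.values())

    def test_constant_offset(self):
        p = np.linspace(0, 1, CYCLE_POINTS)
        base = {j: np.zeros(CYCLE_POINTS) for j in ("hip", "knee", "ankle")}
        shifted = {j: v.copy() for j, v in base.items()}
        shifted["knee"] = shifted["knee"] + 2.0
        c = compare_kinematics(fake_trial(shifted), fake_trial(base))
        assert c.max_diff_deg["knee"] == pytest.approx(2.0)
        assert c.rms_diff_deg["knee"] == pytest.approx(2.0)
        assert c.max_diff_deg["hip"] == 0.0

    def test_sinusoidal_difference_analytic_rms(self):
        p = np.linspace(0, 1, CYCLE_POINTS)
        base = {j: np.zeros(CYCLE_POINTS) for j in ("hip", "knee", "ankle")}
        shifted = {j: v.copy() for j, v in base.items()}
        shifted["hip"] = 3.0 * np.sin(2 * np.pi * p)
        c = compare_kinematics(fake_trial(shifted), fake_trial(base))
        assert c.max_diff_deg["hip"] == pytest.approx(3.0, rel=1e-3)
        assert c.rms_diff_deg["hip"] == pytest.approx(3.0 / math.sqrt(2), rel=0.01)

    def test_fell_trial_propagates_flag_not_numbers(self):
        p = {j: np.zeros(CYCLE_POINTS) for j in ("hip", "knee", "ankle")}
        c = compare_kinematics(fake_trial(dict(p), fell=True), fake_trial(dict(p)))
        assert c.treadmill_fell and not c.overground_fell
        assert all(math.isnan(v) for v in c.rms_diff_deg.values())

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_rms_never_exceeds_max(self, seed):
        rng = np.random.default_rng(seed)
        a = {j: rng.normal(0, 5, CYCLE_POINTS) for j in ("hip", "knee", "ankle")}
        b = {j: rng.normal(0, 5, CYCLE_POINTS) for j in ("hip", "knee", "ankle")}
        c = compare_kinematics(fake_trial(a), fake_trial(b))
        for j in ("hip", "knee", "ankle"):
            assert c.rms_diff_deg[j] <= c.max_diff_deg[j] + 1e-12


class TestDetectFall:
    def test_steady_walking_no_fall(self, overground_trial, model63):
        fell, _ = detect_fall(overground_trial.t, overground_trial.q, model63)
        assert not fell

    def test_height_drop_detected_at_crossing(self, model63):
        t = np.arange(0, 4.0, 1e-3)
        q = np.zeros((len(t), 9))
        h0 = model63.standing_hip_height
        q[:, 1] = h0 * np.clip(1.0 - 0.35 * t / 2.0, 0.3, None)
        fell, tf = detect_fall(t, q, model63)
        assert fell
        # crossing of 0.5·h0 happens when 1 − 0.175·t = 0.5
        assert tf == pytest.approx(0.5 / 0.175, abs=0.01)

    def test_pitch_limit_detected(self, model63):
        t = np.arange(0, 3.0, 1e-3)
        q = np.zeros((len(t), 9))
        q[:, 1] = model63.standing_hip_height
        q[t >= 1.2, 2] = math.radians(70.0)
        fell, tf = detect_fall(t, q, model63)
        assert fell and tf == pytest.approx(1.2, abs=1e-3)


class TestRunTrial:
    def test_deterministic_repeat(self):
        cfg = TrialConfig(speed=1.05, duration=7.2)
        a, b = run_trial(cfg), run_trial(cfg)
        assert np.array_equal(a.q, b.q)
        assert np.array_equal(a.grf, b.grf)
        assert a.mean_reward == b.mean_reward

    def test_short_duration_rejected(self):
        with pytest.raises(ValueError):
            run_trial(TrialConfig(speed=1.05, duration=0.5))

    def test_overground_walk_quality_gate(self, overground_trial):
        # tracking + PD at zero perturbation holds a high mean imitation
        # reward over the retained cycles
        assert not overground_trial.fell
        assert overground_trial.retained_cycles >= 2
        assert overground_trial.mean_reward > 0.9

    def test_contact_force_invariants_along_trial(self, overground_trial):
        fn = overground_trial.grf[:, :, 1]
        ft = overground_trial.grf[:, :, 0]
        assert np.all(fn >= 0.0)
        assert np.all(np.abs(ft) <= 0.9 * fn + 1e-9)

    def test_curves_have_101_points(self, overground_trial):
        for curve in overground_trial.mean_curves.values():
            assert len(curve) == CYCLE_POINTS


class TestExtractGrf:
    def test_static_standing_trial_balance(self):
        n = 3000
        t = np.arange(n) * 1e-3
        grf = np.zeros((n, 4, 2))
        grf[:, :, 1] = 618.0 / 4.0
        trial = fake_trial({}, grf=grf, t=t, events=np.array([0.5, 1.5, 2.5]))
        curves = extract_grf(trial, foot="R")
        assert np.allclose(curves["vertical"], 309.0, atol=1e-9)  # one foot
        assert np.allclose(curves["horizontal"], 0.0)

    def test_swing_phase_unloaded(self, overground_trial):
        curves = extract_grf(overground_trial, foot="R")
        # mid-swing (~75–90% of the cycle from right heel strike)
        assert np.all(np.abs(curves["vertical"][76:90]) < 5.0)

    def test_cycle_mean_supports_body_weight(self, overground_trial):
        left = extract_grf(overground_trial, foot="L")
        right = extract_grf(overground_trial, foot="R")
        total = (left["vertical"] + right["vertical"]).mean()
        assert total == pytest.approx(63.0 * GRAVITY, rel=0.05)

    def test_braking_is_negative_early_stance(self, overground_trial):
        horiz = extract_grf(overground_trial, foot="R")["horizontal"]
        assert horiz[2:15].min() < 0.0

    def test_no_cycles_raises(self):
        with pytest.raises(InsufficientCycles):
            extract_grf(fake_trial({}, retained=0))


class TestRunSweep:
    def test_empty_grid_list_rejected(self):
        with pytest.raises(ValueError):
            run_sweep({"fmax": [], "fctrl": [17], "mass": [63], "speed": [1.05]})

    def test_single_ideal_condition_matches_overground(self):
        df = run_sweep({"fmax": [math.inf], "fctrl": [math.inf],
                        "mass": [63.0], "speed": [1.05]},
                       TrialConfig(duration=12.0))
        assert len(df) == 3  # one condition × three joints
        assert (df["rms_diff_deg"] < 0.1).all()
        assert not df["fell"].any()


class TestConfigRoundtrip:
    def test_yaml_roundtrip_preserves_trial_settings(self, tmp_path):
        cfg = TrialConfig(
            mass=79.0, speed=1.33, duration=9.0, seed=3,
            treadmill=TreadmillSpec(target_speed=1.33, fmax=200.0, fctrl=13.0),
        )
        path = tmp_path / "cfg.yaml"
        save_config(cfg, path, sweep={"fmax": [100.0, 300.0], "fctrl": [17.0],
                                      "mass": [63.0], "speed": [1.05]})
        loaded, sweep = load_config(path)
        assert loaded.mass == 79.0 and loaded.speed == 1.33
        assert loaded.duration == 9.0 and loaded.seed == 3
        assert loaded.treadmill.fmax == 200.0
        assert loaded.treadmill.fctrl == 13.0
        assert sweep["fmax"] == [100.0, 300.0]

    def test_default_config_is_overground(self, tmp_path):
        path = tmp_path / "cfg.yaml"
        path.write_text("model: {mass: 47.0}\n")
        cfg, sweep = load_config(path)
        assert cfg.mass == 47.0
        assert cfg.treadmill is None and sweep is None
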