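"""Overground and treadmill trials, gait-cycle analysis and condition sweeps.

A *trial* drops the biped onto a surface in the reference pose and runs
forward dynamics with the tracking controller for a fixed duration.  The
surface is either stationary ground (overground condition) or the top of
a treadmill belt whose speed is regulated by the saturated, zero-order-
hold PD loop of :mod:`treadgait.treadmill` — or held exactly constant in
ideal (kinematic-belt) mode.  Heel strikes segment the right-leg joint
trajectories into gait cycles, each resampled to 101 points of percent
gait cycle; treadmill-minus-overground differences of the mean cycle
curves give the per-joint maximum and RMS differences that quantify how
belt force and control-frequency limits distort gait.

Reported joint angles are anatomical flexion angles in degrees (hip
flexion +, knee flexion +, ankle dorsiflexion +); internally the model
uses CCW-positive radians (knee flexion is a negative model angle).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable

import numpy as np
import pandas as pd

from . import biped_model as bm
from .biped_model import BipedModel, Surface, build_model
from .controller import (
    PDGains,
    RewardWeights,
    imitation_rewards_batch,
)
from .reference_motion import (
    GaitTemplate,
    ReferenceMotion,
    default_template_for_speed,
    generate_reference,
)
from .treadmill import BeltState, TreadmillSpec, belt_control_force, step_belt

JOINT_REPORT = ("hip", "knee", "ankle")
# model q indices of the right-leg joints and anatomical sign factors
_JOINT_Q_INDEX = {"hip": 6, "knee": 7, "ankle": 8}
_JOINT_SIGN = {"hip": 1.0, "knee": -1.0, "ankle": 1.0}

FALL_HEIGHT_FRACTION = 0.5  # of standing hip height
FALL_PITCH_LIMIT = math.radians(60.0)
EVENT_THRESHOLD_N = 20.0
EVENT_DEBOUNCE_S = 0.1
CYCLE_POINTS = 101


class InsufficientCycles(RuntimeError):
    """A trial did not retain enough gait cycles for analysis."""


@dataclass
class TrialConfig:
    """Everything needed to reproduce one trial deterministically."""

    mass: float = 63.0  # kg
    speed: float = 1.05  # m/s
    treadmill: TreadmillSpec | None = None  # None → overground
    height: float = 1.73  # m
    duration: float = 12.0  # s
    dt: float = 5e-4  # s
    seed: int = 0
    template: GaitTemplate | None = None  # None → default for the speed
    gains: PDGains = field(default_factory=PDGains)
    weights: RewardWeights = field(default_factory=RewardWeights)
    stabilizer: bool = True
    transient_cycles: int = 3
    mu_ground: float = 0.9


@dataclass
class TrialResult:
    config: TrialConfig
    reference: ReferenceMotion
    t: np.ndarray  # (ns,)
    q: np.ndarray  # (ns, 9)
    qd: np.ndarray  # (ns, 9)
    grf: np.ndarray  # (ns, 4, 2) per contact point (heelL,toeL,heelR,toeR)
    belt_speed: np.ndarray  # (ns,) rearward-positive belt speed (0 overground)
    belt_force: np.ndarray  # (ns,) held control force (N)
    events: np.ndarray  # (ne,) right heel-strike times, s
    cycles: dict[str, np.ndarray]  # joint -> (n_cycles, 101) deg
    mean_curves: dict[str, np.ndarray]  # joint -> (101,) deg
    fell: bool
    fall_time: float | None
    mean_reward: float
    retained_cycles: int


@dataclass
class ComparisonResult:
    """Per-joint max and RMS kinematic differences, treadmill − overground."""

    max_diff_deg: dict[str, float]
    rms_diff_deg: dict[str, float]
    treadmill_fell: bool
    overground_fell: bool

    @property
    def any_fell(self) -> bool:
        return self.treadmill_fell or self.overground_fell


def detect_gait_events(
    vgrf: np.ndarray,
    dt: float,
    threshold: float = EVENT_THRESHOLD_N,
    debounce: float = EVENT_DEBOUNCE_S,
    min_unloaded: float = 0.0,
) -> np.ndarray:
    """Heel-strike times: rising crossings of ``threshold`` on one foot's
    vertical GRF, with a debounce window suppressing re-triggers.

    ``min_unloaded`` optionally requires the foot to have been below the
    threshold for that long before a crossing counts — this rejects
    mid-stance unloading blips, which have no preceding swing phase,
    while true heel strikes follow a long unloaded interval.
    """
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    vgrf = np.asarray(vgrf, dtype=float)
    above = vgrf >= threshold
    rising = np.flatnonzero(above[1:] & ~above[:-1]) + 1
    w = int(round(min_unloaded / dt))
    loaded_count = np.concatenate([[0], np.cumsum(above)])
    events: list[float] = []
    for i in rising:
        if w > 0:
            lo = max(i - w, 0)
            if loaded_count[i] - loaded_count[lo] > 0:
                continue  # foot was loaded within the lookback window
        t = i * dt
        if not events or t - events[-1] >= debounce:
            events.append(t)
    return np.asarray(events)


def cycle_normalize(
    t: np.ndarray,
    series: np.ndarray,
    events: np.ndarray,
    n: int = CYCLE_POINTS,
) -> tuple[np.ndarray, np.ndarray]:
    """Resample each inter-strike interval to ``n`` points (0–100% cycle).

    Returns (per-cycle curves (m, n), pointwise mean curve (n,)).
    """
    if len(events) < 2:
        raise InsufficientCycles("need at least 2 gait events")
    if n < 2:
        raise ValueError("n must be >= 2")
    cycles = np.empty((len(events) - 1, n))
    for c in range(len(events) - 1):
        grid = np.linspace(events[c], events[c + 1], n)
        cycles[c] = np.interp(grid, t, series)
    return cycles, cycles.mean(axis=0)


def detect_fall(
    t: np.ndarray, q: np.ndarray, model: BipedModel
) -> tuple[bool, float | None]:
    """Fall = root below half standing hip height, or trunk pitch past 60°."""
    low = q[:, 1] < FALL_HEIGHT_FRACTION * model.standing_hip_height
    tipped = np.abs(q[:, 2]) > FALL_PITCH_LIMIT
    bad = np.flatnonzero(low | tipped)
    if len(bad) == 0:
        return False, None
    return True, float(t[bad[0]])


def run_trial(config: TrialConfig) -> TrialResult:
    """Run one overground or treadmill trial; deterministic for a config."""
    model = build_model(config.mass, config.height)
    template = config.template or default_template_for_speed(config.speed, model)
    ref = generate_reference(config.speed, model, template, seed=config.seed)
    T = ref.cycle_duration
    if config.duration < 5.0 * T:
        raise ValueError(
            f"duration {config.duration} s is below 5 gait cycles ({5 * T:.2f} s)"
        )

    spec = config.treadmill.tuned() if config.treadmill is not None else None
    on_belt = spec is not None
    ideal = on_belt and spec.ideal

    n_steps = int(round(config.duration / config.dt))
    dt = config.dt
    times = np.arange(n_steps) * dt
    phases = np.mod(times / T, 1.0)

    # precompute per-step targets and stabilizer references (open-loop phase)
    targets = ref.angles_at(phases)  # (ns, 6)
    np.clip(targets, model._lim_lo, model._lim_hi, out=targets)
    zp_ref = ref.root_zp_at(phases)  # (ns, 2) z, pitch
    vel_ref = ref.root_vel_at(phases)  # (ns, 3)

    # initial state: reference pose at phase 0, feet kissing the surface
    q = np.zeros(bm.NQ)
    q[1] = ref.root[0, 1]
    q[2] = ref.root[0, 2]
    q[3:] = ref.angles[0]
    pts = model.points(q)
    q[1] -= pts[list(model.CONTACT_POINTS), 1].min()
    qd = np.zeros(bm.NQ)
    qd[3:] = ref.velocities[0]
    qd[1] = ref.root_vel[0, 1]
    qd[0] = 0.0 if on_belt else config.speed

    belt = BeltState(velocity=spec.target_speed if on_belt else 0.0,
                     prev_velocity=spec.target_speed if on_belt else 0.0)
    mu = spec.mu if on_belt else config.mu_ground
    gains = config.gains

    Qtraj = np.empty((n_steps, bm.NQ))
    Qdtraj = np.empty((n_steps, bm.NQ))
    Ftraj = np.empty((n_steps, 4, 2))
    belt_v = np.zeros(n_steps)
    belt_f = np.zeros(n_steps)

    surface = Surface(height=0.0, speed=0.0, mu=mu)
    for k in range(n_steps):
        t = times[k]
        if on_belt:
            surface.speed = -belt.velocity
            if not ideal:
                belt_f[k] = belt_control_force(spec, belt, t)
            belt_v[k] = belt.velocity
        tau = gains.kp * (targets[k] - q[3:]) - gains.kd * qd[3:]
        np.clip(tau, -gains.tau_max, gains.tau_max, out=tau)
        if config.stabilizer:
            fz = gains.height_kp * (zp_ref[k, 0] - q[1]) \
                + gains.height_kd * (vel_ref[k, 1] - qd[1])
            tp = gains.pitch_kp * (zp_ref[k, 1] - q[2]) \
                + gains.pitch_kd * (vel_ref[k, 2] - qd[2])
            wrench = (0.0, fz, tp)
        else:
            wrench = (0.0, 0.0, 0.0)
        qdd, fc = bm._dynamics_rhs(model, q, qd, tau, wrench, surface)
        qd = qd + qdd * dt
        q = q + qd * dt
        Qtraj[k] = q
        Qdtraj[k] = qd
        Ftraj[k] = fc
        if on_belt and not ideal:
            belt = step_belt(
                spec, belt,
                foot_tangential_load=float(fc[:, 0].sum()),
                dt=dt,
                foot_normal_load=float(fc[:, 1].sum()),
            )
        elif ideal:
            belt = step_belt(spec, belt, 0.0, dt)
    if not np.all(np.isfinite(q)):
        raise bm.NumericFailure("trial diverged: non-finite state")

    fell, fall_time = detect_fall(times, Qtraj, model)
    t_end = fall_time if fell else config.duration

    vgrf_r = Ftraj[:, 2, 1] + Ftraj[:, 3, 1]
    # cadence-aware windows: one heel strike per foot per cycle, and a
    # real swing interval must precede it
    events = detect_gait_events(vgrf_r, dt, debounce=0.55 * T,
                                min_unloaded=0.15 * T)
    events = events[(events > 0.0) & (events < t_end - 1e-9)]
    keep = slice(min(config.transient_cycles, max(len(events) - 1, 0)), None)
    events_kept = events[keep]

    cycles: dict[str, np.ndarray] = {}
    mean_curves: dict[str, np.ndarray] = {}
    retained = max(len(events_kept) - 1, 0)
    if retained >= 1:
        for joint in JOINT_REPORT:
            series = np.degrees(_JOINT_SIGN[joint] * Qtraj[:, _JOINT_Q_INDEX[joint]])
            cyc, mean = cycle_normalize(times, series, events_kept)
            cycles[joint] = cyc
            mean_curves[joint] = mean

    # mean imitation reward over the retained window (decimated 10×)
    if len(events_kept) >= 1:
        i0 = int(events_kept[0] / dt)
    else:
        i0 = 0
    idx = np.arange(i0, int(t_end / dt), 10)
    if len(idx) > 0:
        r = imitation_rewards_batch(
            Qtraj[idx], Qdtraj[idx], model, ref, phases[idx], config.weights
        )
        mean_reward = float(r.mean())
    else:
        mean_reward = float("nan")

    return TrialResult(
        config=config, reference=ref, t=times, q=Qtraj, qd=Qdtraj, grf=Ftraj,
        belt_speed=belt_v, belt_force=belt_f, events=events_kept,
        cycles=cycles, mean_curves=mean_curves, fell=fell, fall_time=fall_time,
        mean_reward=mean_reward, retained_cycles=retained,
    )


def compare_kinematics(
    treadmill: TrialResult, overground: TrialResult
) -> ComparisonResult:
    """Max and RMS of (treadmill − overground) mean cycle curves, degrees."""
    if treadmill.fell or overground.fell or treadmill.retained_cycles < 2 \
            or overground.retained_cycles < 2:
        nan = {j: float("nan") for j in JOINT_REPORT}
        return ComparisonResult(nan, dict(nan), treadmill.fell, overground.fell)
    if set(treadmill.mean_curves) != set(overground.mean_curves):
        raise KeyError("joint sets of the two trials do not match")
    max_d, rms_d = {}, {}
    for joint in JOINT_REPORT:
        delta = treadmill.mean_curves[joint] - overground.mean_curves[joint]
        max_d[joint] = float(np.max(np.abs(delta)))
        rms_d[joint] = float(np.sqrt(np.mean(delta**2)))
    return ComparisonResult(max_d, rms_d, False, False)


def extract_grf(trial: TrialResult, foot: str = "R") -> dict[str, np.ndarray]:
    """Cycle-normalized mean GRF curves for one foot (braking negative).

    Returns {"horizontal": (101,), "vertical": (101,)} in newtons versus
    percent gait cycle.
    """
    if trial.retained_cycles < 1:
        raise InsufficientCycles("trial retained no full gait cycles")
    rows = (2, 3) if foot.upper() == "R" else (0, 1)
    fx = trial.grf[:, rows, 0].sum(axis=1)
    fz = trial.grf[:, rows, 1].sum(axis=1)
    _, mean_fx = cycle_normalize(trial.t, fx, trial.events)
    _, mean_fz = cycle_normalize(trial.t, fz, trial.events)
    return {"horizontal": mean_fx, "vertical": mean_fz}


def run_sweep(
    grid: dict[str, Iterable[float]],
    base: TrialConfig | None = None,
) -> pd.DataFrame:
    """Cross-product condition sweep against per-(mass, speed) baselines.

    ``grid`` keys: ``fmax`` (N), ``fctrl`` (Hz), ``mass`` (kg), ``speed``
    (m/s); every list must be non-empty.  One overground baseline trial is
    run per (mass, speed); each treadmill condition is compared against
    it.  Returns a long-format table with one row per condition and joint:
    columns mass_kg, speed_mps, fmax_N, fctrl_Hz, joint, max_diff_deg,
    rms_diff_deg, fell (NaN differences where a trial fell).
    """
    base = base or TrialConfig()
    lists = {k: list(grid.get(k, [])) for k in ("fmax", "fctrl", "mass", "speed")}
    for key, vals in lists.items():
        if not vals:
            raise ValueError(f"sweep grid list '{key}' is empty")

    baselines: dict[tuple[float, float], TrialResult] = {}
    rows = []
    for mass in lists["mass"]:
        for speed in lists["speed"]:
            key = (mass, speed)
            og = replace(base, mass=mass, speed=speed, treadmill=None)
            baselines[key] = run_trial(og)
            for fmax in lists["fmax"]:
                for fctrl in lists["fctrl"]:
                    # an infinite force or rate denotes the ideal belt
                    if not (np.isfinite(fmax) and np.isfinite(fctrl)):
                        spec = TreadmillSpec(target_speed=speed, ideal=True)
                    else:
                        spec = TreadmillSpec(
                            target_speed=speed, fmax=fmax, fctrl=fctrl
                        )
                    tm = run_trial(replace(base, mass=mass, speed=speed,
                                           treadmill=spec))
                    cmpres = compare_kinematics(tm, baselines[key])
                    for joint in JOINT_REPORT:
                        rows.append({
                            "mass_kg": mass, "speed_mps": speed,
                            "fmax_N": fmax, "fctrl_Hz": fctrl, "joint": joint,
                            "max_diff_deg": cmpres.max_diff_deg[joint],
                            "rms_diff_deg": cmpres.rms_diff_deg[joint],
                            "fell": cmpres.any_fell,
                        })
    return pd.DataFrame(rows)
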