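"""Treadmill belt dynamics and discrete PD speed control.

The belt is a single translating inertia (the frame–belt prismatic joint)
driven by a proportional–derivative speed controller that runs at a finite
control frequency: the control force is recomputed only at multiples of
the control period and held constant in between (zero-order hold, ZOH),
and is saturated at a maximum belt force ``fmax`` — the proxy for motor
power.  Stance-foot friction loads and a Coulomb deck friction act on the
same inertia.  An *ideal* belt is a kinematic body: it holds the target
speed exactly regardless of load, which makes its co-moving frame
inertial and treadmill dynamics identical to overground dynamics.

Belt speed is stored as a positive scalar (the speed at which the top
surface travels rearward); the surface material velocity seen by the feet
is ``-speed`` along x.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .biped_model import GRAVITY


@dataclass
class TreadmillSpec:
    """Belt parameters and control settings.

    ``kp``/``kd`` default to None, meaning :func:`auto_tune_gains` is
    applied when the spec is used.
    """

    target_speed: float  # m/s, v*
    fmax: float = 300.0  # N, saturation of the control force
    fctrl: float = 17.0  # Hz, controller update rate
    kp: float | None = None  # N s/m
    kd: float | None = None  # N s^2/m
    m_belt: float = 60.0  # kg, belt + roller + reflected drive inertia
    mu_deck: float = 0.05  # belt–deck sliding friction coefficient
    mu: float = 0.9  # belt–foot friction coefficient
    ideal: bool = False
    v_eps: float = 0.05  # m/s, deck friction regularization

    def __post_init__(self) -> None:
        if self.target_speed < 0:
            raise ValueError("target speed must be >= 0")
        if not self.ideal:
            if self.fmax <= 0 or self.fctrl <= 0:
                raise ValueError("fmax and fctrl must be > 0 for a non-ideal belt")
        if self.m_belt <= 0:
            raise ValueError("belt mass must be > 0")

    def tuned(self) -> "TreadmillSpec":
        """Return a copy with gains filled in via :func:`auto_tune_gains`."""
        if self.ideal or (self.kp is not None and self.kd is not None):
            return self
        kp, kd = auto_tune_gains(self)
        return TreadmillSpec(
            self.target_speed, self.fmax, self.fctrl, kp, kd,
            self.m_belt, self.mu_deck, self.mu, self.ideal, self.v_eps,
        )


@dataclass
class BeltState:
    position: float = 0.0  # m travelled by the belt surface (rearward +)
    velocity: float = 0.0  # m/s, rearward-positive belt speed
    held_force: float = 0.0  # N, last ZOH output of the controller
    last_update: float = -math.inf  # s, time of last controller update
    prev_velocity: float = 0.0  # belt speed at the previous update (for Kd)


def auto_tune_gains(spec: TreadmillSpec) -> tuple[float, float]:
    """Deterministic PD gains for the belt loop.

    For ZOH proportional control of a pure inertia the discrete loop is
    stable for Kp < 2·m·fctrl; we take half that bound, Kp = m·fctrl,
    and a small derivative gain Kd = 0.1·Kp/fctrl.
    """
    if spec.ideal:
        raise ValueError("an ideal belt needs no gains")
    kp = spec.m_belt * spec.fctrl
    kd = 0.1 * kp / spec.fctrl
    return kp, kd


def belt_control_force(spec: TreadmillSpec, belt: BeltState, t: float) -> float:
    """ZOH PD control force at time ``t`` (updates ``belt`` bookkeeping).

    The force is recomputed once each control period 1/fctrl:
    F = clip(Kp·(v* − v_belt) − Kd·a_belt, ±fmax), where a_belt is
    estimated from the belt speeds at the last two controller updates.
    Between updates the previously computed force is returned unchanged.
    """
    if spec.ideal:
        raise ValueError("an ideal belt has no control force")
    period = 1.0 / spec.fctrl
    # update on entering a new control interval: breakpoints stay pinned
    # to multiples of 1/fctrl instead of drifting with the sampling grid
    due = math.floor((t + 1e-12) / period)
    last = (-1 if belt.last_update == -math.inf
            else math.floor((belt.last_update + 1e-12) / period))
    if due > last:
        if belt.last_update == -math.inf:
            accel = 0.0
        else:
            accel = (belt.velocity - belt.prev_velocity) / (t - belt.last_update)
        kp = spec.kp if spec.kp is not None else auto_tune_gains(spec)[0]
        kd = spec.kd if spec.kd is not None else auto_tune_gains(spec)[1]
        force = kp * (spec.target_speed - belt.velocity) - kd * accel
        belt.held_force = float(np.clip(force, -spec.fmax, spec.fmax))
        belt.prev_velocity = belt.velocity
        belt.last_update = t
    return belt.held_force


def step_belt(
    spec: TreadmillSpec,
    belt: BeltState,
    foot_tangential_load: float,
    dt: float,
    foot_normal_load: float = 0.0,
) -> BeltState:
    """Advance the belt one step under the held control force and foot loads.

    ``foot_tangential_load`` is the net x-force the feet exert on the belt
    surface expressed in the rearward-positive belt coordinate (braking
    stance loads are negative: they slow the belt).  ``foot_normal_load``
    (≥ 0) adds to the deck normal load for Coulomb deck friction.  In
    ideal mode the belt is kinematic: speed stays exactly at target.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    if spec.ideal:
        return BeltState(
            position=belt.position + spec.target_speed * dt,
            velocity=spec.target_speed,
            held_force=0.0,
            last_update=belt.last_update,
            prev_velocity=belt.prev_velocity,
        )
    deck = (
        spec.mu_deck
        * (spec.m_belt * GRAVITY + max(foot_normal_load, 0.0))
        * math.tanh(belt.velocity / spec.v_eps)
    )
    dv = (belt.held_force + foot_tangential_load - deck) * dt / spec.m_belt
    v_new = belt.velocity + dv
    return BeltState(
        position=belt.position + v_new * dt,
        velocity=v_new,
        held_force=belt.held_force,
        last_update=belt.last_update,
        prev_velocity=belt.prev_velocity,
    )


def belt_response_oracle(
    spec: TreadmillSpec,
    disturbance: np.ndarray,
    dt: float,
) -> np.ndarray:
    """Reference belt-speed trajectory for a piecewise-constant disturbance.

    Runs the exact discrete recursion of the ZOH PD loop on a pure inertia
    (no deck friction), written independently of the physics stepper:
    within each sample the held force and disturbance are constant, so the
    velocity update v_{n+1} = v_n + (F_held + d_n)·dt/m is exact.  The
    held force is recomputed (and clipped at ±fmax) whenever a sample
    crosses a controller update instant.  Returns speeds at each of the
    ``len(disturbance)`` sample times, starting from the target speed.
    """
    if spec.ideal:
        raise ValueError("oracle applies to the non-ideal belt loop")
    d = np.asarray(disturbance, dtype=float)
    if d.ndim != 1 or len(d) == 0:
        raise ValueError("disturbance profile must be a non-empty 1-D array")
    kp, kd = (spec.kp, spec.kd)
    if kp is None or kd is None:
        kp, kd = auto_tune_gains(spec)
    period = 1.0 / spec.fctrl
    v = spec.target_speed
    v_prev_update = v
    t_last = -math.inf
    held = 0.0
    out = np.empty(len(d))
    for n in range(len(d)):
        t = n * dt
        due = math.floor((t + 1e-12) / period)
        last = -1 if t_last == -math.inf else math.floor((t_last + 1e-12) / period)
        if due > last:
            accel = 0.0 if t_last == -math.inf else (v - v_prev_update) / (t - t_last)
            held = float(np.clip(kp * (spec.target_speed - v) - kd * accel, -spec.fmax, spec.fmax))
            v_prev_update = v
            t_last = t
        out[n] = v
        v = v + (held + d[n]) * dt / spec.m_belt
    return out
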