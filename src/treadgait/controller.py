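"""Gait control and motion-imitation scoring.

The controller tracks a periodic reference motion: at each step the
policy emits target joint angles (the action), a joint-space PD law turns
them into torques, and an optional root stabilizer applies a restoring
pitch torque and vertical force toward the reference root trajectory.
The stabilizer stands in for the balance behaviour a learned policy would
provide; it deliberately applies *no horizontal force*, so belt speed
perturbations still propagate into the kinematics through stance-foot
friction, and the root otherwise remains unactuated.

The imitation rewards score how closely a simulated state tracks the
reference: exponential similarity terms for pose, joint velocity,
end-effector positions and centre of mass (both relative to the root),
combined as r = wp·rp + wv·rv + we·re + wc·rc with default weights
0.65/0.1/0.15/0.1 (summing to one, so perfect tracking scores 1.0).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Protocol

import numpy as np

from .biped_model import BipedModel, SimState
from .reference_motion import ReferenceMotion, SchemaError

OBSERVATION_SIZE = 23
N_TERRAIN = 5
TERRAIN_GRID = np.array([0.2, 0.4, 0.6, 0.8, 1.0])  # m ahead of the root


@dataclass
class RewardWeights:
    wp: float = 0.65
    wv: float = 0.10
    we: float = 0.15
    wc: float = 0.10

    def __post_init__(self) -> None:
        if min(self.wp, self.wv, self.we, self.wc) < 0:
            raise ValueError("reward weights must be non-negative")


@dataclass
class Observation:
    """Planar observation vector (23 entries) in documented packing order."""

    root_height: float
    root_pitch: float
    root_linvel: np.ndarray  # (2,)
    root_angvel: float
    joint_angles: np.ndarray  # (6,)
    joint_velocities: np.ndarray  # (6,)
    phase: float
    terrain: np.ndarray  # (5,) heights at the forward grid points

    def as_vector(self) -> np.ndarray:
        v = np.concatenate([
            [self.root_height, self.root_pitch], self.root_linvel,
            [self.root_angvel], self.joint_angles, self.joint_velocities,
            [self.phase], self.terrain,
        ])
        assert len(v) == OBSERVATION_SIZE
        return v


@dataclass
class Action:
    """Target joint angles (rad) for the six actuated joints."""

    targets: np.ndarray  # (6,)


@dataclass
class PDGains:
    """Joint-space PD gains plus the root-stabilizer gains.

    Defaults: hip/knee 1200/8, ankle 400/4 (N·m/rad, N·m·s/rad); torques
    clipped at ±250 N·m.  Root stabilizer: pitch 2000/200 (N·m/rad,
    N·m·s/rad), height 500/50 (N/m, N·s/m).  The stiff position gains
    with light damping substitute for the torque shaping a trained policy
    would provide: high stiffness carries the stance-leg gravity load,
    and low damping avoids dragging the fast swing leg, whose reference
    speed the pure −kd·θ̇ term would otherwise fight.  The pitch
    stabilizer must exceed the gravitational destabilizing stiffness of
    the trunk (≈ m·g·h_com ≈ 200 N·m/rad at 63 kg) with margin.
    """

    kp: np.ndarray = field(default_factory=lambda: np.array(
        [1200.0, 1200.0, 400.0, 1200.0, 1200.0, 400.0]))
    kd: np.ndarray = field(default_factory=lambda: np.array(
        [8.0, 8.0, 4.0, 8.0, 8.0, 4.0]))
    tau_max: float = 250.0
    pitch_kp: float = 2000.0
    pitch_kd: float = 200.0
    height_kp: float = 500.0
    height_kd: float = 50.0


def assemble_observation(
    model: BipedModel,
    state: SimState,
    phase: float,
    terrain: Callable[[float], float] | None = None,
) -> Observation:
    """Pack the state into the fixed 23-entry observation layout.

    ``terrain`` maps world x to surface height; flat ground (height 0) is
    assumed when omitted.  The stored phase is wrapped into [0, 1).
    """
    terrain = terrain or (lambda x: 0.0)
    xs = state.q[0] + TERRAIN_GRID
    heights = np.array([terrain(float(x)) for x in xs])
    return Observation(
        root_height=float(state.q[1]),
        root_pitch=float(state.q[2]),
        root_linvel=state.qd[:2].copy(),
        root_angvel=float(state.qd[2]),
        joint_angles=state.q[3:].copy(),
        joint_velocities=state.qd[3:].copy(),
        phase=float(np.mod(phase, 1.0)),
        terrain=heights,
    )


class Policy(Protocol):
    """Observation → action; lets a learned policy replace the tracker."""

    def act(self, obs: Observation) -> Action: ...


def tracking_policy(reference: ReferenceMotion, phase: float) -> Action:
    """Deterministic reference-tracking policy: target = θ̂(phase).

    Linear interpolation on the reference phase grid; phase is wrapped
    into [0, 1) by the reference's periodic lookup.
    """
    if reference.angles.shape[1] != 6:
        raise SchemaError("reference does not carry 6 joint-angle columns")
    return Action(targets=np.asarray(reference.angles_at(phase), dtype=float))


@dataclass
class TrackingPolicy:
    """:class:`Policy` wrapper around :func:`tracking_policy`."""

    reference: ReferenceMotion

    def act(self, obs: Observation) -> Action:
        return tracking_policy(self.reference, obs.phase)


def joint_pd_torques(gains: PDGains, action: Action, state: SimState) -> np.ndarray:
    """τ_j = kp_j·(θ_target,j − θ_j) − kd_j·θ̇_j, clipped to ±tau_max."""
    tau = gains.kp * (action.targets - state.q[3:]) - gains.kd * state.qd[3:]
    return np.clip(tau, -gains.tau_max, gains.tau_max)


def root_stabilizer(
    gains: PDGains,
    state: SimState,
    reference: ReferenceMotion,
    phase: float,
) -> tuple[float, float, float]:
    """Restoring root wrench (Fx, Fz, τ_pitch) toward the reference root.

    Fx is always zero: belt perturbations must reach the kinematics
    through the contact path, not be cancelled at the root.  Zero gains
    give a zero wrench, as does a state exactly on the reference
    trajectory (damping acts on the velocity *error*).
    """
    z_ref, pitch_ref = reference.root_zp_at(phase)
    vel_ref = reference.root_vel_at(phase)
    fz = gains.height_kp * (z_ref - state.q[1]) + gains.height_kd * (vel_ref[1] - state.qd[1])
    tau = gains.pitch_kp * (pitch_ref - state.q[2]) + gains.pitch_kd * (vel_ref[2] - state.qd[2])
    return (0.0, float(fz), float(tau))


def imitation_rewards(
    state: SimState,
    model: BipedModel,
    reference: ReferenceMotion,
    phase: float,
    weights: RewardWeights | None = None,
) -> dict[str, float]:
    """Exponential imitation scores {rp, rv, re, rc, r}, each in (0, 1].

    rp = exp[−2·Σ_j (θ̂_j − θ_j)²]          pose
    rv = exp[−0.04·Σ_j (θ̂̇_j − θ̇_j)²]       joint velocity
    re = exp[−40·Σ_e ‖p̂_e − p_e‖²]          end-effectors (feet, rel. root)
    rc = exp[−30·‖p̂_c − p_c‖²]              centre of mass (rel. root)
    r  = wp·rp + wv·rv + we·re + wc·rc
    """
    weights = weights or RewardWeights()
    th_ref = reference.angles_at(phase)
    om_ref = reference.velocities_at(phase)
    ee_ref = reference.ee_at(phase)
    com_ref = reference.com_at(phase)

    pts = model.points(state.q)
    root = state.q[:2]
    ee = np.stack([pts[model.P_ANKLE_L], pts[model.P_ANKLE_R]]) - root
    com = model.masses @ pts[:7] / model.total_mass - root

    rp = float(np.exp(-2.0 * np.sum((th_ref - state.q[3:]) ** 2)))
    rv = float(np.exp(-0.04 * np.sum((om_ref - state.qd[3:]) ** 2)))
    re = float(np.exp(-40.0 * np.sum((ee_ref - ee) ** 2)))
    rc = float(np.exp(-30.0 * np.sum((com_ref - com) ** 2)))
    r = weights.wp * rp + weights.wv * rv + weights.we * re + weights.wc * rc
    return {"rp": rp, "rv": rv, "re": re, "rc": rc, "r": r}


def imitation_rewards_batch(
    Q: np.ndarray,
    Qd: np.ndarray,
    model: BipedModel,
    reference: ReferenceMotion,
    phases: np.ndarray,
    weights: RewardWeights | None = None,
) -> np.ndarray:
    """Vectorized total reward r for (N, 9) trajectory blocks."""
    weights = weights or RewardWeights()
    th_ref = reference.angles_at(phases)
    om_ref = reference.velocities_at(phases)
    ee_ref = reference.ee_at(phases)
    com_ref = reference.com_at(phases)
    pts = model.points_batch(Q)
    root = Q[:, None, :2]
    ee = np.stack([pts[:, model.P_ANKLE_L], pts[:, model.P_ANKLE_R]], axis=1) - root
    com = np.einsum("i,nia->na", model.masses, pts[:, :7]) / model.total_mass - Q[:, :2]
    rp = np.exp(-2.0 * np.sum((th_ref - Q[:, 3:]) ** 2, axis=1))
    rv = np.exp(-0.04 * np.sum((om_ref - Qd[:, 3:]) ** 2, axis=1))
    re = np.exp(-40.0 * np.sum((ee_ref - ee) ** 2, axis=(1, 2)))
    rc = np.exp(-30.0 * np.sum((com_ref - com) ** 2, axis=1))
    return weights.wp * rp + weights.wv * rv + weights.we * re + weights.wc * rc
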