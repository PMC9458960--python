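"""Sagittal-plane floating-base biped: model construction, kinematics, dynamics.

Model layout
------------
Seven rigid segments — HAT (head–arms–trunk), left/right thigh, shank and
foot — connected by six revolute joints (hip, knee, ankle per leg) to a
3-DoF unactuated floating root.  Generalized coordinates::

    q = [root_x (m), root_z (m), trunk_pitch (rad),
         hipL, kneeL, ankleL, hipR, kneeR, ankleR]   (joint angles, rad)

Conventions: x forward, z up, all angles counterclockwise-positive,
g = 9.81 m/s² downward.  In the zero pose the trunk is vertical, the legs
hang straight down and the feet are horizontal.  With these signs,
anatomical hip flexion is a positive hip angle, knee flexion is a
*negative* knee angle, and ankle dorsiflexion is a positive ankle angle.

Dynamics are integrated with a semi-implicit Euler step; foot–ground
contact is a smooth penalty law (linear spring with Hunt–Crossley-style
velocity term for the normal, tanh-regularized Coulomb friction for the
tangential component).  Joint range-of-motion is enforced by stiff
one-sided torsional springs rather than hard constraints.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

GRAVITY = 9.81

NQ = 9
JOINT_NAMES = ("hipL", "kneeL", "ankleL", "hipR", "kneeR", "ankleR")
SEGMENT_NAMES = ("HAT", "thighL", "shankL", "footL", "thighR", "shankR", "footR")
CONTACT_NAMES = ("heelL", "toeL", "heelR", "toeR")

# Winter-style anthropometric fractions (of total mass / standing height).
MASS_FRACTIONS = {"HAT": 0.678, "thigh": 0.100, "shank": 0.0465, "foot": 0.0145}
LENGTH_FRACTIONS = {"thigh": 0.245, "shank": 0.246, "foot": 0.152}
ANKLE_HEIGHT_FRACTION = 0.039  # sole-to-ankle height
HAT_LENGTH_FRACTION = 0.470  # hip to vertex, treated as a slender rod


class NumericFailure(RuntimeError):
    """Raised when a state quantity becomes NaN/Inf during integration."""


@dataclass(frozen=True)
class SegmentSpec:
    """One rigid segment: mass properties and geometry.

    ``com_offset`` is measured from the proximal joint along the segment.
    """

    name: str
    mass: float  # kg
    length: float  # m
    com_offset: float  # m
    inertia: float  # kg m^2, about the CoM

    def __post_init__(self) -> None:
        if self.mass <= 0 or self.length <= 0 or self.inertia <= 0:
            raise ValueError(f"segment {self.name}: mass/length/inertia must be > 0")
        if not 0.0 <= self.com_offset <= self.length:
            raise ValueError(f"segment {self.name}: CoM offset outside segment")


@dataclass
class Surface:
    """A horizontal support surface (ground, or the moving top of a belt)."""

    height: float = 0.0  # m
    speed: float = 0.0  # m/s, signed x-velocity of the surface material
    mu: float = 0.9  # foot–surface friction coefficient


@dataclass
class ContactParams:
    kn: float = 3.0e4  # N/m normal stiffness
    cn: float = 0.5  # s/m Hunt–Crossley damping factor
    v_eps: float = 0.05  # m/s friction regularization velocity


@dataclass
class SimState:
    """Generalized state plus the most recent per-point contact forces."""

    q: np.ndarray  # (9,)
    qd: np.ndarray  # (9,)
    t: float = 0.0
    contact_forces: np.ndarray = field(
        default_factory=lambda: np.zeros((4, 2))
    )  # rows heelL,toeL,heelR,toeR; cols fx,fz (N, force on the foot)

    def copy(self) -> "SimState":
        return SimState(self.q.copy(), self.qd.copy(), self.t, self.contact_forces.copy())

    @property
    def joint_angles(self) -> np.ndarray:
        return self.q[3:]

    @property
    def joint_velocities(self) -> np.ndarray:
        return self.qd[3:]


class BipedModel:
    """Planar 7-segment biped with precomputed kinematic-chain tables.

    Every point of interest (segment CoMs, knee/ankle joints, heel/toe
    contact points) is written as ``root + Σ_t ρ_t·u(α_b(t) + ψ_t)`` with
    ``u(θ) = (sin θ, −cos θ)`` and α the absolute segment angles, which are
    linear in q.  Jacobians and velocity-product terms then follow in
    closed form, giving an exact mass matrix, Coriolis vector and gravity
    vector from the same small set of tables.
    """

    # point indices
    P_COM0 = 0  # 0..6 segment CoMs, aligned with SEGMENT_NAMES
    P_HEEL_L, P_TOE_L, P_HEEL_R, P_TOE_R = 7, 8, 9, 10
    P_KNEE_L, P_ANKLE_L, P_KNEE_R, P_ANKLE_R = 11, 12, 13, 14
    NP = 15
    CONTACT_POINTS = (7, 8, 9, 10)
    END_EFFECTORS = (12, 14)  # ankles

    def __init__(
        self,
        segments: dict[str, SegmentSpec],
        total_mass: float,
        height: float,
        joint_limits: dict[str, tuple[float, float]] | None = None,
        contact: ContactParams | None = None,
        joint_limit_stiffness: float = 500.0,
    ):
        self.segments = segments
        self.total_mass = float(total_mass)
        self.height = float(height)
        self.contact = contact or ContactParams()
        self.joint_limit_stiffness = joint_limit_stiffness
        self.joint_names = JOINT_NAMES
        if joint_limits is None:
            hip, knee, ankle = (-0.7, 2.1), (-2.6, 0.1), (-1.2, 1.2)
            joint_limits = {
                "hipL": hip, "kneeL": knee, "ankleL": ankle,
                "hipR": hip, "kneeR": knee, "ankleR": ankle,
            }
        self.joint_limits = joint_limits
        self._lim_lo = np.array([joint_limits[j][0] for j in JOINT_NAMES])
        self._lim_hi = np.array([joint_limits[j][1] for j in JOINT_NAMES])

        seg_mass = sum(s.mass for s in segments.values())
        if abs(seg_mass - total_mass) > 1e-9:
            raise ValueError("segment masses do not sum to the total mass")

        self.masses = np.array([segments[n].mass for n in SEGMENT_NAMES])
        self.inertias = np.array([segments[n].inertia for n in SEGMENT_NAMES])
        self._build_tables()

    # -- construction of the chain tables ---------------------------------

    def _build_tables(self) -> None:
        seg = self.segments
        l_th = seg["thighL"].length
        l_sh = seg["shankL"].length
        l_ft = seg["footL"].length
        c_hat = seg["HAT"].com_offset
        c_th = seg["thighL"].com_offset
        c_sh = seg["shankL"].com_offset
        h_a = self.ankle_height = ANKLE_HEIGHT_FRACTION * self.height

        # local foot-frame offsets (forward f, up g) relative to the ankle;
        # the ankle sits 25% of foot length behind the toe-end of the sole
        heel_local = (-0.25 * l_ft, -h_a)
        toe_local = (0.75 * l_ft, -h_a)
        fcom_local = (0.25 * l_ft, -0.5 * h_a)

        def rot_term(body: int, local: tuple[float, float]) -> tuple[int, float, float]:
            f, g = local
            return (body, math.hypot(f, g), math.atan2(g, f) + 0.5 * math.pi)

        # absolute-angle composition matrix: alpha = Aang @ q[2:]
        Aang = np.zeros((7, 7))
        Aang[0, 0] = 1.0  # HAT: pitch
        for side, (b0, j0) in (("L", (1, 1)), ("R", (4, 4))):
            Aang[b0, 0] = Aang[b0 + 1, 0] = Aang[b0 + 2, 0] = 1.0  # pitch
            Aang[b0, j0] = 1.0  # thigh: + hip
            Aang[b0 + 1, j0] = Aang[b0 + 1, j0 + 1] = 1.0  # shank: + hip + knee
            Aang[b0 + 2, j0:j0 + 3] = 1.0  # foot: + hip + knee + ankle
        self.Aang = Aang

        terms: list[tuple[int, int, float, float]] = []  # (point, body, rho, psi)

        def chain(point: int, *ts: tuple[int, float, float]) -> None:
            for body, rho, psi in ts:
                terms.append((point, body, rho, psi))

        for side, b0 in (("L", 1), ("R", 4)):
            th, sh, ft = b0, b0 + 1, b0 + 2
            heel = self.P_HEEL_L if side == "L" else self.P_HEEL_R
            toe = self.P_TOE_L if side == "L" else self.P_TOE_R
            knee = self.P_KNEE_L if side == "L" else self.P_KNEE_R
            ankle = self.P_ANKLE_L if side == "L" else self.P_ANKLE_R
            chain(th, (th, c_th, 0.0))  # thigh CoM
            chain(sh, (th, l_th, 0.0), (sh, c_sh, 0.0))  # shank CoM
            chain(ft, (th, l_th, 0.0), (sh, l_sh, 0.0), rot_term(ft, fcom_local))
            chain(knee, (th, l_th, 0.0))
            chain(ankle, (th, l_th, 0.0), (sh, l_sh, 0.0))
            chain(heel, (th, l_th, 0.0), (sh, l_sh, 0.0), rot_term(ft, heel_local))
            chain(toe, (th, l_th, 0.0), (sh, l_sh, 0.0), rot_term(ft, toe_local))
        chain(0, (0, c_hat, math.pi))  # HAT CoM points up from the root

        self.term_point = np.array([t[0] for t in terms], dtype=np.intp)
        self.term_body = np.array([t[1] for t in terms], dtype=np.intp)
        self.term_rho = np.array([t[2] for t in terms])
        self.term_psi = np.array([t[3] for t in terms])
        self.P = np.zeros((self.NP, len(terms)))
        self.P[self.term_point, np.arange(len(terms))] = 1.0
        self._A_terms = Aang[self.term_body]  # (NT, 7)
        # constant rotational part of the mass matrix
        A9 = np.zeros((7, NQ))
        A9[:, 2:] = Aang
        self._M_rot = A9.T @ np.diag(self.inertias) @ A9
        self.standing_hip_height = l_th + l_sh + h_a

    # -- kinematics --------------------------------------------------------

    def _term_vectors(self, q: np.ndarray):
        """sin/cos machinery shared by all kinematic evaluations."""
        alpha = self.Aang @ q[2:]
        theta = alpha[self.term_body] + self.term_psi
        st, ct = np.sin(theta), np.cos(theta)
        vec = np.empty((len(theta), 2))
        vec[:, 0] = self.term_rho * st
        vec[:, 1] = -self.term_rho * ct
        dvec = np.empty_like(vec)
        dvec[:, 0] = self.term_rho * ct
        dvec[:, 1] = self.term_rho * st
        return alpha, vec, dvec

    def points(self, q: np.ndarray) -> np.ndarray:
        """Positions (NP, 2) of all points of interest."""
        q = np.asarray(q, dtype=float)
        if q.shape != (NQ,):
            raise ValueError(f"q must have {NQ} entries, got {q.shape}")
        _, vec, _ = self._term_vectors(q)
        return q[:2][None, :] + self.P @ vec

    def points_batch(self, Q: np.ndarray) -> np.ndarray:
        """Vectorized :meth:`points` for a (N, 9) block of configurations."""
        Q = np.asarray(Q, dtype=float)
        alpha = Q[:, 2:] @ self.Aang.T  # (N, 7)
        theta = alpha[:, self.term_body] + self.term_psi  # (N, NT)
        vec = np.stack(
            [self.term_rho * np.sin(theta), -self.term_rho * np.cos(theta)], axis=-1
        )
        return Q[:, None, :2] + np.einsum("pt,nta->npa", self.P, vec)

    def point_kinematics(self, q: np.ndarray, qd: np.ndarray):
        """Positions, velocities, Jacobians and velocity-product terms.

        Returns ``(pts, vels, J, bias, rel_vels)`` with shapes (NP,2),
        (NP,2), (NP,2,9), (NP,2), (NP,2): ``vels = J qd``,
        ``bias = (dJ/dt) qd`` and ``rel_vels`` the angle-induced part of
        the point velocities (``vels`` minus the root velocity).  The
        split lets contact friction form point velocities *relative to a
        moving surface* without mixing in the absolute root velocity,
        keeping the arithmetic identical between a ground frame and a
        co-moving belt frame (Galilean equivalence to round-off).
        """
        alpha, vec, dvec = self._term_vectors(q)
        alphad = self.Aang @ qd[2:]
        ad_t = alphad[self.term_body]
        pts = q[:2][None, :] + self.P @ vec
        rel_vels = self.P @ (dvec * ad_t[:, None])
        vels = qd[:2][None, :] + rel_vels
        bias = self.P @ (-vec * (ad_t**2)[:, None])
        J = np.zeros((self.NP, 2, NQ))
        J[:, 0, 0] = 1.0
        J[:, 1, 1] = 1.0
        J[:, :, 2:] = np.einsum("pt,ta,tj->paj", self.P, dvec, self._A_terms)
        return pts, vels, J, bias, rel_vels

    def mass_matrix(self, q: np.ndarray) -> np.ndarray:
        _, _, J, _, _ = self.point_kinematics(np.asarray(q, float), np.zeros(NQ))
        Jc = J[:7]
        return np.einsum("i,iaj,iak->jk", self.masses, Jc, Jc) + self._M_rot

    def com(self, q: np.ndarray) -> np.ndarray:
        """Whole-body centre of mass (2,)."""
        pts = self.points(q)
        return self.masses @ pts[:7] / self.total_mass


def build_model(
    total_mass: float,
    height: float,
    contact: ContactParams | None = None,
) -> BipedModel:
    """Construct the biped from total mass (kg) and standing height (m).

    Segment masses and lengths follow fixed anthropometric fractions, so
    scaling ``total_mass`` scales every segment mass proportionally while
    the geometry is unchanged — matching the virtual-subject protocol in
    which body mass varies on an identical skeleton.
    """
    if total_mass <= 0 or height <= 0:
        raise ValueError("total_mass and height must be > 0")

    def rod(name: str, m: float, length: float, com_frac: float) -> SegmentSpec:
        return SegmentSpec(name, m, length, com_frac * length, m * length**2 / 12.0)

    l_th = LENGTH_FRACTIONS["thigh"] * height
    l_sh = LENGTH_FRACTIONS["shank"] * height
    l_ft = LENGTH_FRACTIONS["foot"] * height
    h_a = ANKLE_HEIGHT_FRACTION * height
    m_hat = MASS_FRACTIONS["HAT"] * total_mass
    m_th = MASS_FRACTIONS["thigh"] * total_mass
    m_sh = MASS_FRACTIONS["shank"] * total_mass
    m_ft = MASS_FRACTIONS["foot"] * total_mass

    segments = {"HAT": rod("HAT", m_hat, HAT_LENGTH_FRACTION * height, 0.626)}
    for side in ("L", "R"):
        segments[f"thigh{side}"] = rod(f"thigh{side}", m_th, l_th, 0.433)
        segments[f"shank{side}"] = rod(f"shank{side}", m_sh, l_sh, 0.433)
        segments[f"foot{side}"] = SegmentSpec(
            f"foot{side}", m_ft, l_ft, 0.5 * l_ft, m_ft * (l_ft**2 + h_a**2) / 12.0
        )
    return BipedModel(segments, total_mass, height, contact=contact)


def forward_kinematics(model: BipedModel, q: np.ndarray) -> dict[str, np.ndarray]:
    """Named positions of joints, contact points, segment CoMs and body CoM."""
    pts = model.points(q)
    out: dict[str, np.ndarray] = {}
    for i, name in enumerate(SEGMENT_NAMES):
        out[f"com_{name}"] = pts[i]
    for idx, name in zip(model.CONTACT_POINTS, CONTACT_NAMES):
        out[name] = pts[idx]
    out["kneeL"], out["ankleL"] = pts[model.P_KNEE_L], pts[model.P_ANKLE_L]
    out["kneeR"], out["ankleR"] = pts[model.P_KNEE_R], pts[model.P_ANKLE_R]
    out["hip"] = np.asarray(q, float)[:2].copy()
    out["com"] = model.masses @ pts[:7] / model.total_mass
    return out


def contact_point_forces(
    model: BipedModel,
    pts: np.ndarray,
    rel_vels: np.ndarray,
    root_vel: np.ndarray,
    surface: Surface,
) -> np.ndarray:
    """Penalty contact forces (4, 2) on the feet at the four contact points.

    Normal: fN = kn·δ·(1 + cn·δ̇), clipped at zero (δ = penetration depth).
    Tangential: fT = −μ·fN·tanh(v_rel/v_eps) with v_rel the horizontal
    point velocity relative to the surface material, formed as
    ``(root_vx − surface.speed) + rel_v`` so that a ground frame and a
    co-moving belt frame evaluate identical floating-point expressions.
    """
    cp = model.contact
    f = np.zeros((4, 2))
    dvx = root_vel[0] - surface.speed
    for k, idx in enumerate(model.CONTACT_POINTS):
        delta = surface.height - pts[idx, 1]
        if delta <= 0.0:
            continue
        delta_dot = -(root_vel[1] + rel_vels[idx, 1])
        fn = cp.kn * delta * (1.0 + cp.cn * delta_dot)
        if fn < 0.0:
            fn = 0.0
        v_rel = dvx + rel_vels[idx, 0]
        f[k, 0] = -surface.mu * fn * math.tanh(v_rel / cp.v_eps)
        f[k, 1] = fn
    return f


def contact_forces(model: BipedModel, state: SimState, surface: Surface) -> np.ndarray:
    """Contact forces (4, 2) for a full state; see :func:`contact_point_forces`."""
    if surface.mu <= 0:
        raise ValueError("surface friction coefficient must be > 0")
    pts, _, _, _, rel = model.point_kinematics(state.q, state.qd)
    return contact_point_forces(model, pts, rel, state.qd[:2], surface)


def joint_limit_torques(model: BipedModel, q: np.ndarray) -> np.ndarray:
    """One-sided torsional-spring torques (6,) beyond the joint limits."""
    th = q[3:]
    k = model.joint_limit_stiffness
    low = np.minimum(th - model._lim_lo, 0.0)
    high = np.maximum(th - model._lim_hi, 0.0)
    return -k * (low + high)


def _dynamics_rhs(
    model: BipedModel,
    q: np.ndarray,
    qd: np.ndarray,
    torques: np.ndarray,
    external_wrench: tuple[float, float, float],
    surface: Surface,
):
    """Generalized acceleration and contact forces at (q, qd)."""
    pts, vels, J, bias, rel = model.point_kinematics(q, qd)
    Jc = J[:7]
    M = np.einsum("i,iaj,iak->jk", model.masses, Jc, Jc) + model._M_rot
    h = np.einsum("i,iaj,ia->j", model.masses, Jc, bias[:7])
    Qg = -GRAVITY * (model.masses @ Jc[:, 1, :])

    fc = contact_point_forces(model, pts, rel, qd[:2], surface)
    Q = Qg - h
    for k, idx in enumerate(model.CONTACT_POINTS):
        if fc[k, 1] != 0.0 or fc[k, 0] != 0.0:
            Q += J[idx].T @ fc[k]
    Q[1] += external_wrench[1]
    Q[2] += external_wrench[2]
    Q[0] += external_wrench[0]
    Q[3:] += torques + joint_limit_torques(model, q)
    qdd = np.linalg.solve(M, Q)
    return qdd, fc


def step_dynamics(
    model: BipedModel,
    state: SimState,
    torques: np.ndarray,
    external_wrench: tuple[float, float, float] = (0.0, 0.0, 0.0),
    surface: Surface | None = None,
    dt: float = 5e-4,
) -> SimState:
    """One semi-implicit Euler step of M(q)q̈ = Q(q, q̇).

    ``torques`` are the six joint torques (the root is unactuated);
    ``external_wrench`` is an (Fx, Fz, τ_pitch) load applied at the root.
    Contact forces evaluated at the pre-step state are recorded in the
    returned :class:`SimState`.
    """
    if not 0.0 < dt <= 2e-3:
        raise ValueError("dt must lie in (0, 2e-3] s")
    torques = np.asarray(torques, dtype=float)
    if torques.shape != (6,):
        raise ValueError("expected 6 joint torques")
    if surface is None:
        surface = Surface(height=-1e9)  # effectively no ground
    if not np.all(np.isfinite(state.q)):
        bad = JOINT_NAMES[max(0, int(np.flatnonzero(~np.isfinite(state.q))[0]) - 3)]
        raise NumericFailure(f"non-finite coordinate near joint {bad}")
    if not np.all(np.isfinite(state.qd)):
        raise NumericFailure("non-finite generalized velocity")

    qdd, fc = _dynamics_rhs(model, state.q, state.qd, torques, external_wrench, surface)
    if not np.all(np.isfinite(qdd)):
        raise NumericFailure("non-finite generalized acceleration")
    qd_new = state.qd + qdd * dt
    q_new = state.q + qd_new * dt
    return SimState(q_new, qd_new, state.t + dt, fc)


def total_energy(model: BipedModel, state: SimState) -> float:
    """Kinetic (½ q̇ᵀM q̇) plus gravitational potential energy (J)."""
    M = model.mass_matrix(state.q)
    ke = 0.5 * state.qd @ M @ state.qd
    pts = model.points(state.q)
    pe = GRAVITY * float(model.masses @ pts[:7, 1])
    return float(ke + pe)
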