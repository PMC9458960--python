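"""Synthetic periodic reference gait: the target motion the controller tracks.

The measured subject motions behind the original experiment are not
available, so this module synthesizes sagittal-plane reference gaits that
are *kinematically consistent with the ground* by construction.  For a
requested speed the builder designs world-frame foot trajectories — a
flat-foot stance phase with the foot stationary on the ground, a toe-pivot
push-off, and a clearance swing — together with a vaulting root-height
arc, solves the two-link hip/knee inverse kinematics at every phase
sample, and fits each joint trajectory with a truncated Fourier series
(order ≤ 5).  A :class:`GaitTemplate` carries the fitted per-joint
coefficient table plus the cadence model T(v) and root-arc parameters.
The two legs share coefficients with a half-cycle phase shift (symmetric
gait); phase 0 corresponds to right heel strike.

Because angles are stored as finite Fourier series, stored velocities are
exact analytic derivatives and periodicity is exact; the consistency
checker verifies both, plus the mean forward root speed.  Where the leg
cannot geometrically reach the designed foot point (deep trailing
positions at long strides) the inverse kinematics saturates at near-full
extension, so the realized gait slips slightly instead of producing
impossible joint angles.

Anatomical sign mapping to the model convention (CCW-positive): hip
flexion → +hip angle, knee flexion → −knee angle, dorsiflexion → +ankle
angle.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .biped_model import NQ, BipedModel, JOINT_NAMES

FOURIER_ORDER = 5
MOTION_SCHEMA = "treadgait-motion v1"
WALK_RUN_SPEED_SPLIT = 2.0  # m/s
_DESIGN_SAMPLES = 720  # dense grid used for IK + Fourier fitting


class SchemaError(ValueError):
    """A motion file or template does not match the documented schema."""


@dataclass
class FourierSeries:
    """a0 + Σ_k a_k cos(2πkφ) + b_k sin(2πkφ), k = 1..order."""

    a0: float
    a: np.ndarray
    b: np.ndarray

    def __call__(self, phi: np.ndarray) -> np.ndarray:
        phi = np.asarray(phi, dtype=float)
        k = np.arange(1, len(self.a) + 1)
        ang = 2.0 * np.pi * np.multiply.outer(phi, k)
        return self.a0 + np.cos(ang) @ self.a + np.sin(ang) @ self.b

    def dphi(self, phi: np.ndarray) -> np.ndarray:
        """Derivative with respect to phase."""
        phi = np.asarray(phi, dtype=float)
        k = np.arange(1, len(self.a) + 1)
        w = 2.0 * np.pi * k
        ang = 2.0 * np.pi * np.multiply.outer(phi, k)
        return -np.sin(ang) @ (w * self.a) + np.cos(ang) @ (w * self.b)


def _fit_series(phi: np.ndarray, y: np.ndarray, order: int = FOURIER_ORDER) -> FourierSeries:
    """Least-squares Fourier fit of a periodic sampled curve."""
    k = np.arange(1, order + 1)
    ang = 2.0 * np.pi * np.multiply.outer(phi, k)
    X = np.hstack([np.ones((len(phi), 1)), np.cos(ang), np.sin(ang)])
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    return FourierSeries(float(coef[0]), coef[1 : order + 1], coef[order + 1 :])


@dataclass
class CadenceModel:
    """Gait-cycle duration T(v) in seconds as a function of speed (m/s)."""

    t_ref: float = 1.4  # s at v_ref
    slope: float = 0.45  # s per m/s (duration shortens as speed rises)
    v_ref: float = 1.05  # m/s
    t_min: float = 0.7
    t_max: float = 1.9

    def __call__(self, speed: float) -> float:
        return float(np.clip(self.t_ref - self.slope * (speed - self.v_ref),
                             self.t_min, self.t_max))


@dataclass
class GaitShape:
    """Designer parameters of the foot/root trajectory (walk or run)."""

    duty: float = 0.60  # stance fraction of the cycle
    heel_off: float = 0.42  # phase at which the toe pivot begins
    push_angle: float = math.radians(25.0)  # max foot pitch during push-off
    knee_hs: float = math.radians(5.0)  # knee flexion at heel strike
    knee_mid: float = math.radians(8.0)  # knee flexion at mid-stance
    clearance: float = 0.02  # m, extra mid-swing foot lift
    root_drop: float = 0.06  # m, root height drop from mid-stance to double support
    sag: float = 0.0  # m, root-arc lowering anticipating contact/joint compliance


WALK_SHAPE = GaitShape()
RUN_SHAPE = GaitShape(
    duty=0.35, heel_off=0.22, push_angle=math.radians(30.0),
    knee_hs=math.radians(12.0), knee_mid=math.radians(15.0),
    clearance=0.05, root_drop=0.07,
)


@dataclass
class GaitTemplate:
    """Fitted per-joint Fourier table plus cadence and root-arc parameters.

    ``coeffs`` maps joint base names (hip, knee, ankle — right leg) to
    :class:`FourierSeries` in model sign convention (radians).  The root
    height follows z(φ) = z_mean − z_amp·cos(4π(φ − z_peak_phase)),
    peaking at mid-stance.
    """

    coeffs: dict[str, FourierSeries]
    cadence: CadenceModel
    mode: str  # "walk" or "run"
    base_speed: float  # m/s the table was fitted at
    z_mean: float  # m
    z_amp: float  # m
    z_peak_phase: float = 0.30
    noise_amp: float = 0.0  # rad, seeded coefficient perturbation (off by default)
    fit_rms: float = 0.0  # rad, RMS Fourier fit residual (diagnostic)

    def joint_base_names(self) -> tuple[str, ...]:
        return tuple(self.coeffs)


def _quintic(u: np.ndarray, y0: float, dy0: float, y1: float, dy1: float) -> np.ndarray:
    """Quintic Hermite on u ∈ [0,1] with zero end accelerations."""
    h00 = 1 - 10 * u**3 + 15 * u**4 - 6 * u**5
    h10 = u - 6 * u**3 + 8 * u**4 - 3 * u**5
    h01 = 10 * u**3 - 15 * u**4 + 6 * u**5
    h11 = -4 * u**3 + 7 * u**4 - 3 * u**5
    return y0 * h00 + dy0 * h10 + y1 * h01 + dy1 * h11


def _design_leg(
    model: BipedModel, speed: float, T: float, shape: GaitShape
) -> tuple[np.ndarray, dict[str, np.ndarray], float, float, float]:
    """Design one leg's joint trajectories over a dense phase grid.

    Returns (phi grid, {hip,knee,ankle} model-convention angles, z_mean,
    z_amp).  Phase 0 = heel strike of this leg.
    """
    L1 = model.segments["thighL"].length
    L2 = model.segments["shankL"].length
    Lf = model.segments["footL"].length
    h_a = model.ankle_height
    d_toe = 0.75 * Lf  # ankle → toe
    S = speed * T
    ds, pho, gmax = shape.duty, shape.heel_off, shape.push_angle
    Dmax = 0.998 * (L1 + L2)

    def chord(k: float) -> float:
        return math.sqrt(L1**2 + L2**2 + 2 * L1 * L2 * math.cos(k))

    z_mid = h_a + chord(shape.knee_mid)
    z_ds = z_mid - shape.root_drop
    # lead-foot placement: as far ahead as the heel-strike pose can reach
    a_lead = math.sqrt(max(chord(shape.knee_hs) ** 2 - (z_ds - h_a) ** 2, 1e-4))
    a_lead = min(a_lead, 0.5 * S * ds)

    phi = np.linspace(0.0, 1.0, _DESIGN_SAMPLES, endpoint=False)
    # root height arc: minima at double support (just after HS), maximum
    # mid-stance; two oscillations per cycle
    zc = 0.5 * (z_mid + z_ds) - shape.sag
    za = 0.5 * (z_mid - z_ds)
    z_peak = 0.5 * (pho + 0.0) + 0.15  # ≈ mid single-support
    z_root = zc - za * np.cos(4.0 * np.pi * (phi - z_peak))

    ank = np.zeros((_DESIGN_SAMPLES, 2))
    beta = np.zeros(_DESIGN_SAMPLES)  # absolute foot pitch
    x_toe = a_lead + d_toe

    flat = phi <= pho
    ank[flat, 0] = a_lead
    ank[flat, 1] = h_a

    pivot = (phi > pho) & (phi <= ds)
    u = (phi[pivot] - pho) / (ds - pho)
    b = -gmax * u**2
    beta[pivot] = b
    ank[pivot, 0] = x_toe + (-d_toe) * np.cos(b) - h_a * np.sin(b)
    ank[pivot, 1] = (-d_toe) * np.sin(b) + h_a * np.cos(b)

    # swing: from the toe-off pose back to the next heel strike (x + S)
    swing = phi > ds
    u = (phi[swing] - ds) / (1.0 - ds)
    b_to = -gmax
    x_to = x_toe - d_toe * math.cos(b_to) - h_a * math.sin(b_to)
    z_to = -d_toe * math.sin(b_to) + h_a * math.cos(b_to)
    # end derivatives in phase units; stance ankle is stationary (slope 0)
    db = -2.0 * gmax / (ds - pho)
    dx_to = (d_toe * math.sin(b_to) - h_a * math.cos(b_to)) * db
    dz_to = (-d_toe * math.cos(b_to) - h_a * math.sin(b_to)) * db
    ank[swing, 0] = _quintic(u, x_to, dx_to * (1 - ds), a_lead + S, 0.0)
    ank[swing, 1] = _quintic(u, z_to, dz_to * (1 - ds), h_a, 0.0) \
        + shape.clearance * np.sin(np.pi * u) ** 2
    beta[swing] = b_to * 0.5 * (1.0 + np.cos(np.pi * np.minimum(u / 0.6, 1.0)))

    # inverse kinematics: hip at (S·φ, z_root)
    dx = ank[:, 0] - S * phi
    dz = ank[:, 1] - z_root
    D = np.hypot(dx, dz)
    # smooth saturation at near-full extension keeps the fitted joint
    # curves free of kinks where the designed foot point is out of reach
    w = 0.01
    D = Dmax - w * np.logaddexp(0.0, (Dmax - D) / w) * w / w
    D = np.maximum(D, abs(L1 - L2) + 1e-6)
    cos_int = np.clip((D**2 - L1**2 - L2**2) / (2.0 * L1 * L2), -1.0, 1.0)
    k_int = np.arccos(cos_int)  # interior flexion angle, >= 0
    knee = -k_int  # model convention
    # thigh leads the hip→ankle chord by the triangle angle
    delta = np.arctan2(L2 * np.sin(k_int), L1 + L2 * np.cos(k_int))
    hip = np.arctan2(dx, -dz) + delta
    ankle = beta - hip - knee
    return phi, {"hip": hip, "knee": knee, "ankle": ankle}, zc, za, z_peak


def build_template(
    model: BipedModel,
    speed: float,
    shape: GaitShape | None = None,
    cadence: CadenceModel | None = None,
) -> GaitTemplate:
    """Design and Fourier-fit a gait template for one model and speed."""
    if speed <= 0:
        raise ValueError("speed must be > 0")
    mode = "walk" if speed <= WALK_RUN_SPEED_SPLIT else "run"
    if shape is None:
        shape = WALK_SHAPE if mode == "walk" else RUN_SHAPE
    if cadence is None:
        cadence = CadenceModel() if mode == "walk" else CadenceModel(
            t_ref=0.70, slope=0.0, v_ref=3.91, t_min=0.70, t_max=0.70)
    T = cadence(speed)
    phi, curves, zc, za, z_peak = _design_leg(model, speed, T, shape)
    coeffs: dict[str, FourierSeries] = {}
    resid = 0.0
    for joint, y in curves.items():
        fs = _fit_series(phi, y)
        coeffs[joint] = fs
        resid = max(resid, float(np.sqrt(np.mean((fs(phi) - y) ** 2))))
    return GaitTemplate(coeffs, cadence, mode, float(speed),
                        z_mean=zc, z_amp=za, z_peak_phase=z_peak, fit_rms=resid)


def default_template_for_speed(speed: float, model: BipedModel) -> GaitTemplate:
    return build_template(model, speed)


@dataclass
class ReferenceMotion:
    """One canonical gait cycle on a uniform phase grid φ ∈ [0, 1].

    The grid includes both endpoints (n samples, n−1 intervals); by
    periodicity the first and last samples coincide for every periodic
    field, which the consistency checker verifies directly.
    ``angles``/``velocities`` are (n, 6) in model joint order
    (hipL, kneeL, ankleL, hipR, kneeR, ankleR), radians and rad/s.
    ``root`` is (n, 3): x, z (m), pitch (rad); ``root_vel`` its time
    derivative.  ``ee`` is (n, 2, 2): per-foot (L, R) end-effector
    (ankle) positions relative to the root; ``com`` (n, 2) likewise.
    """

    phase: np.ndarray
    angles: np.ndarray
    velocities: np.ndarray
    root: np.ndarray
    root_vel: np.ndarray
    ee: np.ndarray
    com: np.ndarray
    cycle_duration: float  # s
    speed: float  # m/s

    @property
    def n(self) -> int:
        return len(self.phase)

    def _interp(self, table: np.ndarray, phi: float | np.ndarray) -> np.ndarray:
        phi = np.mod(phi, 1.0)
        flat = table.reshape(self.n, -1)
        cols = [np.interp(phi, self.phase, flat[:, c]) for c in range(flat.shape[1])]
        out = np.stack(cols, axis=-1)
        return out.reshape(np.shape(phi) + table.shape[1:])

    def angles_at(self, phi):
        return self._interp(self.angles, phi)

    def velocities_at(self, phi):
        return self._interp(self.velocities, phi)

    def root_zp_at(self, phi):
        """(z, pitch) at phase (root x is not periodic and excluded)."""
        return self._interp(self.root[:, 1:], phi)

    def root_vel_at(self, phi):
        return self._interp(self.root_vel, phi)

    def ee_at(self, phi):
        return self._interp(self.ee, phi)

    def com_at(self, phi):
        return self._interp(self.com, phi)


def generate_reference(
    speed: float,
    model: BipedModel,
    template: GaitTemplate | None = None,
    seed: int = 0,
    n: int = 1001,
) -> ReferenceMotion:
    """Generate one periodic reference gait cycle at the given speed.

    With ``template=None`` a template is designed for this model and
    speed via :func:`build_template`.  End-effector and CoM trajectories
    are computed by forward kinematics of ``model`` at each phase sample.
    Deterministic for a fixed seed; the seeded coefficient noise defaults
    to amplitude 0.
    """
    if speed <= 0:
        raise ValueError("speed must be > 0")
    if template is None:
        template = build_template(model, speed)
    if template.mode == "walk" and speed > WALK_RUN_SPEED_SPLIT:
        raise ValueError("walk template is limited to speeds <= 2.0 m/s")
    if template.mode == "run" and speed <= WALK_RUN_SPEED_SPLIT:
        raise ValueError("run template expects speeds > 2.0 m/s")
    missing = {f"{j}{s}" for j in template.joint_base_names() for s in "LR"} - set(JOINT_NAMES)
    if missing:
        raise SchemaError(f"template joints not in model: {sorted(missing)}")

    T = template.cadence(speed)
    rng = np.random.default_rng(seed)
    series: dict[str, FourierSeries] = {}
    for joint, fs in template.coeffs.items():
        if template.noise_amp > 0.0:
            fs = FourierSeries(
                fs.a0,
                fs.a + rng.normal(0.0, template.noise_amp, len(fs.a)),
                fs.b + rng.normal(0.0, template.noise_amp, len(fs.b)),
            )
        series[joint] = fs

    phi = np.linspace(0.0, 1.0, n)
    angles = np.empty((n, 6))
    vels = np.empty((n, 6))
    for j, joint in enumerate(("hip", "knee", "ankle")):
        fs = series[joint]
        angles[:, 3 + j] = fs(phi)  # right leg at phase φ
        vels[:, 3 + j] = fs.dphi(phi) / T
        shifted = np.mod(phi + 0.5, 1.0)  # left leg, half-cycle shift
        angles[:, j] = fs(shifted)
        vels[:, j] = fs.dphi(shifted) / T

    root = np.zeros((n, 3))
    root[:, 0] = speed * T * phi
    w = 4.0 * np.pi
    root[:, 1] = template.z_mean - template.z_amp * np.cos(w * (phi - template.z_peak_phase))
    root_vel = np.zeros((n, 3))
    root_vel[:, 0] = speed
    root_vel[:, 1] = template.z_amp * w * np.sin(w * (phi - template.z_peak_phase)) / T

    Q = np.zeros((n, NQ))
    Q[:, :2] = root[:, :2]
    Q[:, 2] = root[:, 2]
    Q[:, 3:] = angles
    pts = model.points_batch(Q)
    ee = np.stack([pts[:, model.P_ANKLE_L], pts[:, model.P_ANKLE_R]], axis=1)
    ee -= root[:, None, :2]
    com = np.einsum("i,nia->na", model.masses, pts[:, :7]) / model.total_mass - root[:, :2]

    return ReferenceMotion(phi, angles, vels, root, root_vel, ee, com, T, float(speed))


@dataclass
class ConsistencyReport:
    max_velocity_mismatch: float  # rad/s, stored θ̇ vs finite difference of θ
    speed_error_pct: float  # % deviation of mean root speed from nominal
    periodicity_gap: float  # rad, max |θ(0) − θ(1)|
    velocity_ok: bool
    speed_ok: bool
    periodicity_ok: bool

    @property
    def passed(self) -> bool:
        return self.velocity_ok and self.speed_ok and self.periodicity_ok


def kinematic_consistency_check(
    motion: ReferenceMotion,
    model: BipedModel,
    vel_tol: float = 1e-3,
    speed_tol_pct: float = 1.0,
    period_tol: float = 1e-9,
) -> ConsistencyReport:
    """Verify the stored motion against its own defining invariants.

    Velocities are recomputed by central finite differences of the stored
    angles (independent of the analytic-derivative path), the mean
    forward speed from root displacement per cycle, and the periodicity
    gap by comparing the first and last grid samples.
    """
    if motion.angles.shape[1] != len(model.joint_names):
        raise SchemaError("motion joint count does not match the model")
    th = motion.angles
    n = motion.n
    dphi = 1.0 / (n - 1)
    fd = (th[2:] - th[:-2]) / (2.0 * dphi) / motion.cycle_duration
    max_mismatch = float(np.max(np.abs(fd - motion.velocities[1:-1])))
    mean_speed = (motion.root[-1, 0] - motion.root[0, 0]) / motion.cycle_duration
    speed_err = abs(mean_speed - motion.speed) / motion.speed * 100.0
    gap = float(np.max(np.abs(th[-1] - th[0])))
    return ConsistencyReport(
        max_mismatch, speed_err, gap,
        max_mismatch < vel_tol, speed_err < speed_tol_pct, gap < period_tol,
    )


# -- CSV persistence ------------------------------------------------------

def _columns() -> list[str]:
    cols = ["phase"]
    cols += [f"angle_{j}" for j in JOINT_NAMES]
    cols += [f"vel_{j}" for j in JOINT_NAMES]
    cols += ["root_x", "root_z", "root_pitch", "rootvel_x", "rootvel_z", "rootvel_pitch"]
    cols += ["ee_L_x", "ee_L_z", "ee_R_x", "ee_R_z", "com_x", "com_z"]
    return cols


def save_motion(motion: ReferenceMotion, path) -> None:
    """Write the motion as a versioned CSV (one row per phase sample)."""
    data = np.hstack([
        motion.phase[:, None], motion.angles, motion.velocities,
        motion.root, motion.root_vel,
        motion.ee.reshape(motion.n, 4), motion.com,
    ])
    df = pd.DataFrame(data, columns=_columns())
    with open(path, "w") as fh:
        fh.write(f"# {MOTION_SCHEMA}\n")
        fh.write(f"# cycle_duration={motion.cycle_duration!r}\n")
        fh.write(f"# speed={motion.speed!r}\n")
        df.to_csv(fh, index=False, float_format="%.17g")


def load_motion(path) -> ReferenceMotion:
    """Read a motion CSV written by :func:`save_motion` (full precision)."""
    try:
        with open(path) as fh:
            header = fh.readline().strip()
            if not header.startswith("#") or MOTION_SCHEMA not in header:
                raise SchemaError(
                    f"missing '# {MOTION_SCHEMA}' header line in {path}"
                )
            meta: dict[str, float] = {}
            pos = fh.tell()
            line = fh.readline()
            while line.startswith("#"):
                key, _, val = line[1:].strip().partition("=")
                meta[key.strip()] = float(val)
                pos = fh.tell()
                line = fh.readline()
            fh.seek(pos)
            df = pd.read_csv(fh)
    except OSError as exc:
        raise IOError(f"cannot read motion file {path}: {exc}") from exc
    missing = [c for c in _columns() if c not in df.columns]
    if missing:
        raise SchemaError(f"motion CSV missing column(s): {missing}")
    if "cycle_duration" not in meta or "speed" not in meta:
        raise SchemaError("motion CSV missing cycle_duration/speed metadata")
    n = len(df)
    if n == 0:
        raise SchemaError("motion CSV contains no samples")
    arr = df[_columns()].to_numpy(float)
    return ReferenceMotion(
        phase=arr[:, 0],
        angles=arr[:, 1:7],
        velocities=arr[:, 7:13],
        root=arr[:, 13:16],
        root_vel=arr[:, 16:19],
        ee=arr[:, 19:23].reshape(n, 2, 2),
        com=arr[:, 23:25],
        cycle_duration=meta["cycle_duration"],
        speed=meta["speed"],
    )
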