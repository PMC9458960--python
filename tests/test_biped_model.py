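"""Model construction, kinematics, contact law and integrator physics."""

import math

import numpy as np
import pytest

from treadgait.biped_model import (
    GRAVITY,
    NQ,
    NumericFailure,
    SimState,
    Surface,
    build_model,
    contact_forces,
    forward_kinematics,
    step_dynamics,
    total_energy,
)

M, H = 63.0, 1.73
WEIGHT = M * GRAVITY


@pytest.fixture()
def model():
    return build_model(M, H)


def standing_state(model, dz=0.0):
    q = np.zeros(NQ)
    q[1] = model.standing_hip_height + dz
    return SimState(q, np.zeros(NQ))


class TestBuildModel:
    def test_hat_mass_fraction(self, model):
        assert model.segments["HAT"].mass == pytest.approx(0.678 * 63, abs=1e-12)

    def test_mass_scaling_is_proportional(self, model):
        big = build_model(1.5 * M, H)
        assert big.total_mass == pytest.approx(94.5)
        for name, seg in model.segments.items():
            assert big.segments[name].mass == pytest.approx(1.5 * seg.mass)
            assert big.segments[name].length == seg.length

    def test_segment_masses_sum_to_total(self, model):
        assert sum(s.mass for s in model.segments.values()) == pytest.approx(
            M, abs=1e-9)

    @pytest.mark.parametrize("mass,height", [(0.0, 1.7), (-5.0, 1.7), (63.0, 0.0)])
    def test_invalid_arguments(self, mass, height):
        with pytest.raises(ValueError):
            build_model(mass, height)


class TestForwardKinematics:
    def test_zero_pose_feet_below_hip(self, model):
        fk = forward_kinematics(model, standing_state(model).q)
        for pt in ("heelL", "toeL", "heelR", "toeR"):
            assert fk[pt][1] == pytest.approx(0.0, abs=1e-12)
        assert fk["ankleL"][0] == pytest.approx(0.0, abs=1e-12)

    def test_rigid_translation(self, model):
        rng = np.random.default_rng(3)
        q = rng.normal(0.0, 0.5, NQ)
        fk0 = forward_kinematics(model, q)
        q2 = q.copy()
        q2[0] += 1.0
        fk1 = forward_kinematics(model, q2)
        for key, val in fk0.items():
            assert fk1[key][0] - val[0] == pytest.approx(1.0, abs=1e-12)
            assert fk1[key][1] == pytest.approx(val[1], abs=1e-12)

    def test_whole_body_com_is_mass_weighted_mean(self, model):
        rng = np.random.default_rng(4)
        q = rng.normal(0.0, 0.4, NQ)
        fk = forward_kinematics(model, q)
        num = sum(model.segments[n].mass * fk[f"com_{n}"]
                  for n in model.segments)
        manual = num / model.total_mass
        assert np.allclose(fk["com"], manual, atol=1e-12)

    def test_wrong_q_length_raises(self, model):
        with pytest.raises(ValueError):
            model.points(np.zeros(5))


class TestContact:
    def test_no_force_above_surface(self, model):
        st = standing_state(model, dz=0.005)
        f = contact_forces(model, st, Surface(0.0, 0.0, 0.9))
        assert np.all(f == 0.0)

    def test_normal_force_spring_law(self, model):
        st = standing_state(model, dz=-0.001)  # 1 mm penetration, at rest
        f = contact_forces(model, st, Surface(0.0, 0.0, 0.9))
        assert np.allclose(f[:, 1], model.contact.kn * 1e-3, rtol=1e-9)

    def test_friction_tanh_saturation_bound(self, model):
        st = standing_state(model, dz=-0.001)
        st.qd[0] = 10.0 * model.contact.v_eps
        f = contact_forces(model, st, Surface(0.0, 0.0, 0.9))
        fn = f[:, 1]
        assert np.all(np.abs(f[:, 0]) <= 0.9 * fn)
        assert np.allclose(np.abs(f[:, 0]), 0.9 * fn * math.tanh(10.0), rtol=1e-6)

    def test_invalid_friction_coefficient(self, model):
        with pytest.raises(ValueError):
            contact_forces(model, standing_state(model), Surface(0.0, 0.0, 0.0))


class TestStepDynamics:
    def test_free_fall_closed_form(self, model):
        st = standing_state(model)
        dt = 1e-3
        for _ in range(100):
            st = step_dynamics(model, st, np.zeros(6), dt=dt)
        assert st.qd[1] == pytest.approx(-GRAVITY * 0.1, abs=1e-9)

    def test_force_free_uniform_motion_keeps_angles(self, model):
        # in free fall gravity accelerates every segment equally, so
        # uniform relative motion persists (equivalence principle)
        st = standing_state(model)
        st.q[3], st.q[4], st.q[6] = 0.3, -0.5, -0.2
        st.qd[0], st.qd[1] = 2.0, 1.0
        q0 = st.q[2:].copy()
        for _ in range(1000):
            st = step_dynamics(model, st, np.zeros(6), dt=1e-3)
        assert np.allclose(st.q[2:], q0, atol=1e-9)

    def test_passive_swing_energy_drift_below_one_percent(self, model):
        # gravity on, no contact; drift measured against the natural
        # energy scale m·g·H of the model
        st = standing_state(model)
        st.q[3], st.q[4], st.q[7] = 0.4, -0.6, -0.3
        e0 = total_energy(model, st)
        for _ in range(20000):
            st = step_dynamics(model, st, np.zeros(6), dt=1e-4)
        drift = abs(total_energy(model, st) - e0)
        assert drift < 0.01 * M * GRAVITY * H

    def test_rejects_bad_dt_and_torques(self, model):
        st = standing_state(model)
        with pytest.raises(ValueError):
            step_dynamics(model, st, np.zeros(6), dt=5e-3)
        with pytest.raises(ValueError):
            step_dynamics(model, st, np.zeros(4), dt=1e-4)

    def test_numeric_failure_named(self, model):
        st = standing_state(model)
        st.qd[4] = np.nan
        with pytest.raises(NumericFailure):
            step_dynamics(model, st, np.zeros(6), dt=1e-4)


class TestEnergy:
    def test_static_energy_is_potential_only(self, model):
        st = standing_state(model)
        pts = model.points(st.q)
        pe = GRAVITY * float(model.masses @ pts[:7, 1])
        assert total_energy(model, st) == pytest.approx(pe, abs=1e-9)

    def test_uniform_velocity_kinetic_identity(self, model):
        rng = np.random.default_rng(5)
        q = rng.normal(0.0, 0.4, NQ)
        st = SimState(q, np.zeros(NQ))
        st.qd[0], st.qd[1] = 1.7, -0.4
        ke = total_energy(model, st) - total_energy(model, SimState(q, np.zeros(NQ)))
        v2 = 1.7**2 + 0.4**2
        assert ke == pytest.approx(0.5 * M * v2, abs=1e-9)

    def test_energy_invariant_to_x_translation(self, model):
        st = standing_state(model)
        e0 = total_energy(model, st)
        st.q[0] += 13.7
        assert total_energy(model, st) == pytest.approx(e0, abs=1e-9)


class TestStructuralProperties:
    def test_mass_matrix_spd_at_random_configurations(self, model):
        rng = np.random.default_rng(11)
        for _ in range(100):
            q = rng.normal(0.0, 0.8, NQ)
            Mq = model.mass_matrix(q)
            assert np.allclose(Mq, Mq.T, atol=1e-10)
            assert np.linalg.eigvalsh(Mq).min() > 0.0

    def test_static_standing_supports_body_weight(self, model):
        # PD-held zero pose on flat ground; after settling the total
        # vertical GRF balances gravity
        kp = np.array([1200.0, 1200.0, 400.0] * 2)
        kd = np.array([8.0, 8.0, 4.0] * 2)
        surf = Surface(0.0, 0.0, 0.9)
        st = standing_state(model, dz=-0.002)
        dt = 5e-4
        for _ in range(int(1.0 / dt)):
            tau = np.clip(kp * -st.q[3:] - kd * st.qd[3:], -250, 250)
            st = step_dynamics(model, st, tau, surface=surf, dt=dt)
        samples = []
        for _ in range(400):
            tau = np.clip(kp * -st.q[3:] - kd * st.qd[3:], -250, 250)
            st = step_dynamics(model, st, tau, surface=surf, dt=dt)
            samples.append(st.contact_forces[:, 1].sum())
        assert np.mean(samples) == pytest.approx(WEIGHT, rel=0.01)

    def test_galilean_invariance_of_joint_dynamics(self, model):
        # PD-held standing on a surface moving at s, with the initial
        # root velocity shifted by s, reproduces the s = 0 joint
        # trajectories.  The state is settled to contact equilibrium
        # first so both runs follow the same smooth (event-free) flow and
        # the comparison probes the dynamics, not contact-onset timing.
        kp = np.array([1200.0, 1200.0, 400.0] * 2)
        kd = np.array([8.0, 8.0, 4.0] * 2)

        def pd(st):
            return np.clip(kp * -st.q[3:] - kd * st.qd[3:], -250, 250)

        st = standing_state(model, dz=-0.002)
        for _ in range(3000):
            st = step_dynamics(model, st, pd(st), surface=Surface(0, 0, 0.9),
                               dt=5e-4)
        settled = st

        s = 0.8
        histories = []
        for surf_speed, vshift in ((0.0, 0.0), (-s, -s)):
            st = settled.copy()
            st.qd[0] += vshift
            surf = Surface(0.0, surf_speed, 0.9)
            hist = []
            for _ in range(2000):
                st = step_dynamics(model, st, pd(st), surface=surf, dt=5e-4)
                hist.append(st.q[2:].copy())
            histories.append(np.array(hist))
        assert np.max(np.abs(histories[0] - histories[1])) < 1e-6
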