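# Methods

`treadgait` simulates one virtual subject walking overground and on a
treadmill with the *same* gait controller, and quantifies how the belt's
finite force and finite control rate change lower-limb kinematics.  This
note records the models, the parameters that matter, and the design
choices made where the design was genuinely open.

## Biped model

The body is a sagittal-plane, 7-segment rigid-body chain: a combined
head–arms–trunk (HAT) segment and, per leg, thigh, shank and foot.  The
floating root (pelvis/hip point) contributes 3 unactuated degrees of
freedom (x, z, pitch); the six revolute joints (hip, knee, ankle per
leg) are torque-actuated, for 9 DoF in total.  Conventions: x forward,
z up, angles counterclockwise-positive, g = 9.81 m/s².  Anatomical hip
flexion maps to a positive hip angle, knee flexion to a negative knee
angle, dorsiflexion to a positive ankle angle; reported curves are
converted to anatomical degrees.

Anthropometry uses Winter-style fractions of total mass M and standing
height H: segment masses 0.678·M (HAT), 0.100·M (thigh), 0.0465·M
(shank), 0.0145·M (foot); lengths 0.245·H (thigh), 0.246·H (shank),
0.152·H (foot), ankle height 0.039·H.  Segments are slender rods (feet:
thin boxes) for inertia.  Scaling body mass scales every segment mass
proportionally on fixed geometry, matching the study protocol of
identical skeletons with different masses (47–95 kg around the 63 kg /
1.73 m subject).

Equations of motion are assembled exactly from closed-form point
Jacobians of the planar chain (mass matrix, Coriolis/centrifugal vector,
gravity vector) and integrated with semi-implicit Euler at dt = 0.5 ms
(physics tests use 0.1 ms).  Accuracy is bounded by an energy-drift
test: a passive 2 s swing under gravity drifts by far less than 1% of
the natural energy scale m·g·H.

**Contact** is a smooth penalty law at two points per foot (heel, toe):
normal force fN = kn·δ·(1 + cn·δ̇) clipped at zero (kn = 3·10⁴ N/m,
cn = 0.5 s/m), tangential force −μ·fN·tanh(v_rel/v_ε) with μ = 0.9 and
v_ε = 0.05 m/s.  The relative velocity is formed as
(root velocity − surface speed) + angle-induced part, which makes the
floating-point arithmetic identical between a ground frame and a belt
co-moving frame; the Galilean-equivalence tests rely on this.  Joint
range of motion is enforced by one-sided torsional springs
(500 N·m/rad), not hard constraints.

## Reference gait

The original experiment tracked one subject's motion-capture gait; those
data are unavailable, so the package synthesizes its reference motions.
Hand-authored "normative waveform" tables proved kinematically
inconsistent with a flat-foot planar model (several cm of foot–ground
error), so the generator instead *designs* world-frame foot trajectories
that are consistent with the ground by construction — a flat-foot stance
with the foot stationary, a toe-pivot push-off (foot pitching up to 25°
about the fixed toe), and a clearance swing (quintic Hermite with
matched end velocities plus a sin² lift bump) — together with a vaulting
root-height arc (two oscillations per cycle, 6 cm drop from mid-stance
to double support).  Two-link inverse kinematics (hip, knee) then yields
joint trajectories at every phase sample; the ankle keeps the foot flat
in stance and follows the pivot in push-off.  Where a designed foot
point is out of reach (deep trailing positions at long strides) the
IK saturates smoothly near full extension, so the realized gait slips
slightly rather than producing impossible angles; consequently the
walker's realized speed can deviate a few percent from nominal, which
none of the comparisons depend on.

Each joint trajectory is least-squares fitted with a Fourier series of
order 5 (fit residual ≲ 3° RMS), giving exact periodicity and analytic
velocities; both legs share coefficients with a half-cycle phase shift.
Cycle duration follows T(v) = clamp(1.4 − 0.45·(v − 1.05), 0.7, 1.9) s
for walking and T = 0.70 s for the 3.91 m/s run.  The consistency
checker verifies periodicity (< 1e-9 rad), stored-versus-finite-
difference velocities (< 1e-3 rad/s on the 1001-point grid) and mean
forward root speed (< 1%).  A seeded coefficient-noise option exists for
robustness studies and defaults to zero, so all core results are
deterministic.

## Gait controller

The trained policy network of the original study is out of scope; the
controller here is a deterministic reference-tracking policy behind a
small `Policy` protocol (observation → action), so a learned policy
could be substituted.  At each step the policy emits the reference joint
angles at the current open-loop phase (t/T mod 1); a joint-space PD law
converts them to torques, τ = kp(θ̂ − θ) − kd·θ̇, clipped at ±250 N·m.

Defaults: hip/knee kp = 1200 N·m/rad with kd = 8 N·m·s/rad, ankle
400/4.  The stiffness is deliberately high and the damping deliberately
low: the stance leg must carry gravity loads a trained policy would
compensate by shifting its targets (at 300 N·m/rad the model sags
~10–15° and falls), and a large −kd·θ̇ term fights the swing leg's fast
reference motion.

A root stabilizer stands in for the learned balance behaviour: a
restoring pitch torque (kp = 2000 N·m/rad, kd = 200 — the gravitational
destabilizing stiffness of the trunk is ≈ m·g·h ≈ 204 N·m/rad at 63 kg,
so the gain must exceed that with margin) and a vertical force toward
the reference root height (500 N/m, 50 N·s/m; stronger vertical gains
visibly bias the cycle-mean vertical GRF away from body weight).
Crucially the stabilizer applies **no horizontal force**: belt speed
fluctuations must reach the kinematics through stance-foot friction,
and the root stays unactuated along the direction of travel.

The imitation rewards score tracking quality exactly as in motion-
imitation learning: rp = exp[−2Σ(θ̂−θ)²], rv = exp[−0.04Σ(θ̂̇−θ̇)²],
re = exp[−40Σ‖p̂e−pe‖²] over the two feet (positions relative to the
root), rc = exp[−30‖p̂c−pc‖²] for the centre of mass, combined with
weights 0.65/0.1/0.15/0.1.  The default overground trial holds a mean
cycle reward above 0.9.

## Treadmill

The belt is a single translating inertia (prismatic frame–belt joint)
with equivalent mass 60 kg — belt, rollers and reflected drive inertia;
at the 10 kg of a bare belt the speed-control forces stay below 100 N
and the maximum-force grid never binds, erasing the effect under study.
A PD speed controller runs at fctrl ∈ {10, 13, 17, 25, 50} Hz with
zero-order hold (force recomputed only at multiples of 1/fctrl, pinned
to the period grid) and saturation at Fmax ∈ {100…500} N.  Gains come
from a deterministic rule, Kp = m_belt·fctrl — half the discrete
stability bound Kp < 2·m_belt·fctrl for ZOH P-control of an inertia —
and Kd = 0.1·Kp/fctrl, with belt acceleration estimated from the last
two controller samples.  Coulomb deck friction (μ_deck = 0.05, tanh-
regularized) loads the belt together with the stance-foot reactions.
Speed-error control (not position) is used, the standard reading of
"maintain the desired belt speed".

The *ideal* belt is a kinematic body: speed identically equal to target
regardless of load.  Its co-moving frame is inertial, so treadmill and
overground dynamics are mathematically identical — the pipeline's
central identity check.

An independent oracle (`belt_response_oracle`) re-implements the exact
discrete recursion of the ZOH loop on a pure inertia and must agree with
the physics-path belt stepping to < 1e-4 m/s on a 2 s step-disturbance
run; the P-controlled steady state sits at F/Kp.

## Trials and analysis

A trial initializes the model in the reference pose at phase 0, feet
just touching the surface, with root velocity matched to the
environment (overground: forward v; treadmill: zero over a belt at v),
and runs 12 s by default (10 s for the secondary speeds) — enough for
at least 5 retained cycles after the first 3 are discarded as transient.
Heel strikes are rising crossings of 20 N on a foot's vertical GRF; the
trial runner additionally requires a preceding unloaded interval of
0.15·T (mid-stance unloading blips have no swing phase before them) and
uses a 0.55·T debounce.  Each inter-strike interval is linearly
resampled to 101 points of percent gait cycle; mean curves are pointwise
means over retained cycles.  Comparisons report per-joint maximum and
RMS of (treadmill − overground) mean curves in degrees; a fall (root
below half standing hip height or |trunk pitch| > 60°) propagates as a
categorical outcome instead of numbers.  One trial per condition is run,
and the full default sweep is bit-reproducible.

### Numerical choices and scales

- Default sweep: 5 forces × 5 frequencies at 63 kg / 1.05 m/s
  (25 treadmill trials + 1 baseline), ~12 s simulated time per trial at
  dt = 0.5 ms.  Grid values of ∞ denote the ideal belt.
- The per-step Galilean check uses a 0.3 s window: beyond the first
  contact-state transitions, event-time quantization (a touchdown
  landing one integrator step apart in the two frames) amplifies
  round-off into a small bounded limit-cycle offset, which is why the
  full-trial identity is asserted on cycle-mean curves instead.
- The belt-trend tests allow 0.2° slack (and the pure-belt pulse tests
  2 mm/s) for ripple where the PD force grazes the saturation boundary.

## What the synthetic data do and do not show

The generator emulates periodic, bilaterally symmetric, ground-
consistent sagittal gait at controlled speeds — the features the belt
mechanism interacts with.  It does not emulate a specific subject's
waveforms, cycle-to-cycle variability, 3-D pelvis/arm dynamics, or the
adaptive balance of a trained policy.  Passing tests therefore show
that the *mechanism* — finite belt force and control rate perturbing
gait through stance friction, vanishing exactly for an ideal belt — is
correctly implemented and directionally faithful; they do not reproduce
the original study's numeric tables, which depend on unavailable motion
data and stochastic policy training.  Two known departures: the
kinematic response to body mass is nearly flat here (the belt-speed
perturbation deepens with mass as expected, but mass-independent
controller gains damp the differential response), and fast running on a
weak belt degrades much more strongly than walking.

## Known limitations

Planar model (no 3-D joints, arms or lumbar); flat-foot contact without
heel-to-toe rollover at heel strike; deterministic tracking instead of
learned control, with an explicit (vertical + pitch only) root
stabilizer; penalty contact rather than hard constraints; one trial per
condition.  These are deliberate reductions that keep every result
exactly reproducible on one CPU.
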