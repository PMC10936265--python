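# Methods

## The model

The system is a sagittal-plane (x forward, z up) constrained multibody
model of a person lifting a 10-kg box, optionally wearing a passive+active
back-support exoskeleton:

* **Human** — 11 rigid segments, 13 generalized coordinates: a 3-DOF
  floating pelvis base and ten revolutes (ankle, knee, hip with left/right
  limbs merged; five lumbar joints from L5/S1 to L1/L2; shoulder; elbow).
  The torso segment carries L1, the thorax, head and neck.  Segment
  masses, CoM locations and moments of inertia are scaled from de-Leva
  style segment-inertia fractions by stature (1.69 m) and body mass
  (76.5 kg); the fraction table lives in `data/default_config.yaml` and is
  renormalized at load time so masses sum exactly to body mass.
* **Box** — one free planar body (3 DOF), 10 kg, 0.30 x 0.30 m, resting
  0.42 m ahead of the ankles; the handle is the top edge mid-point.
* **Exoskeleton** — 6 segments, 8 coordinates: a thigh module (3-DOF
  base), an actuated exo-hip revolute to the pelvis module, a
  misalignment-compensation revolute to a small pelvis interface, a trunk
  module (3-DOF base), and two 0-DOF mounts carrying the beam root and
  rollers.  Total mass 9.12 kg, concentrated at pelvis/thigh level.

Dynamics follow `M(q) qdd + h(q, qd) = Q + G(q)^T lambda` with holonomic
constraint rows: feet-ground weld (always), box-ground weld (until
liftoff), hands-box weld (from contact), four lumbar coupling rows
(always) and eight human-device attachment rows (thigh weld, pelvis pin,
trunk weld) when the exoskeleton is worn.  The index-3 DAE is reduced to
index 1; forward simulations use Baumgarte stabilization with gains
2*alpha = 10 s^-1, beta^2 = 25 s^-2 (critically damped pairing) and an
adaptive Runge-Kutta integrator at rtol 1e-8.

### Lumbar spine

The five lumbar joints share the total flexion angle theta_L linearly:
joint i carries the fraction c_i, with c = (0.21, 0.25, 0.22, 0.18, 0.14)
from L5/S1 upward (an in-vivo coordination distribution; only the
constraints sum(c) = 1 and positivity are treated as hard requirements —
the individual values are configuration).  Four linear rows between
neighbouring joints leave the chain one sagittal DOF.  Extension biases
(15, 12, 9, 6, 3 deg) pose the resting lordosis at theta_L = 0; the
matching sacral-slope offset on L5 keeps the torso vertical in neutral
standing.  Because only the c-weighted torque sum is determined by the
coupled dynamics, the per-joint torque split is resolved analytically as
the minimizer of the normalized-torque cost subject to the net
requirement (tau_i proportional to c_i M_max_i^2) — precisely the split a
torque-regularized optimization converges to.

The reported L5/S1 moment is deliberately a separate code path: a
Newton-Euler balance of every body above the joint (vertebrae, torso,
arms, the airborne box, with the hand-box and trunk-attachment wrenches
as external actions), extension-positive.  It is independent of the
torque split.

### Beam element

The carbon-fiber pack (3 rods, 4.7 mm diameter, E = 166 GPa, so
EI = n E pi d^4 / 64 ≈ 11.9 N m^2) is a massless force element between
the pelvis-module mount and the rollers on the trunk module.  Each
instant, the roller position is expressed in the pelvis-fixed beam frame
(axial coordinate L, transverse deltaL) and a cubic spline is fitted to
the boundary conditions delta(0) = delta'(0) = 0 (rigid mount),
delta(1) = deltaL, delta''(1) = 0 (rollers carry no moment).
Small-deflection Euler-Bernoulli theory then gives the tip shear
3 EI deltaL / L^3 on the rollers and the equilibrating force plus
clamping moment 3 EI deltaL / L^2 at the mount.  The small-deflection
assumption is retained even in deep flexion where deltaL/L exceeds the
nominal validity bound 0.3 (a warning is logged); the roller separation
(~0.65 m standing) was chosen so the passive assist at deep flexion is a
few tens of N m, consistent with published passive back-support devices.
The 25-N m hydraulic hip actuator enters as a generalized force on the
exo-hip coordinate, driven by a normalized control |u| <= 1.  Note that
the actuator offloads the hip, not the lumbar joints directly; since the
risk objectives penalize lumbar torques and hip torque only through the
small regularization, the predicted motor usage is close to zero and the
device's lumbar relief comes almost entirely from the passive beams.

## Risk metrics

Analysis side (used for all reported numbers): CLBL is the time integral
(trapezoid) of the signed extension-positive L5/S1 moment over the whole
motion (N m s); PLBL is its maximum (N m).  Optimization side: the
integrands sum the five normalized lumbar joint torques squared
(cumulative surrogate), to the fourth power (peak surrogate), or both
(hybrid); being even in the torque they close the sign loophole of the
signed integral.  All problems add a small all-joint torque
regularization (weight 1e-3) and, with the device, a motor-effort term
(weight 5e-2) so the exoskeleton is not used gratuitously.  M_max
defaults to 250 N m per lumbar joint (a configurable normalization, not a
physiological claim).

## Trajectory optimization

Each of the eight study blocks ({human-only, with-exoskeleton} x
{tracking, CLBL, PLBL, HYB}) is a three-phase problem: stand-to-touch,
load transfer (hand force ramps from zero to the box weight while the box
stays grounded), lift-to-stand.  The transcription is inverse-dynamics
collocation in reduced coordinates:

* With the feet planted and the lumbar chain coupled, the human has six
  independent coordinates (ankle, knee, hip, theta_L, shoulder, elbow).
  A closed-form map reconstructs the full 16/24-coordinate state —
  pelvis base by rooting the chain at the foot, box pose from the ground
  or the hand frame, exoskeleton pose from the attachment closure (a
  two-link solve for the exo-hip and interface angles).  Every kinematic
  constraint of the active phase is therefore satisfied exactly, and the
  equations of motion hold at the samples by construction of the batched
  inverse dynamics.
* Decision variables: knot values of the six coordinates (4 intervals
  per phase, 13 knots, cubic spline with clamped ends so the motion is
  rest-to-rest), free phase durations in [0.2, 3.0] s (fixed to the
  reference timing in the tracking blocks), the phase-2 hand-wrench
  profile (statically indeterminate, hence a control; pinned to zero at
  touch and to the full box weight at liftoff), and the exo control u at
  the knots.
* Collocation samples are the knots plus all interval midpoints (27
  samples), so the integrands and path constraints see twice the knot
  resolution; joint-range windows are additionally checked at midpoints.
  A small knot-curvature penalty (weight 5e-5) discourages inter-node
  oscillation that the grid cannot see — a motion-smoothness prior.
* Path constraints: vertical ground reactions >= 0, friction cones
  (mu = 0.8) at feet and hands, open-grip hand-moment bound (15 N m),
  joint-torque limits, attachment interaction-force limits (±200 N /
  ±60 N m per weld row), |u| <= 1.  Hand-pose equalities pin the hands to
  the handle throughout phase 2, with zero hand velocity at contact
  onset (impact-free transitions).
* The dense NLP (~75-90 variables) is solved by SLSQP with 2-point
  finite-difference gradients (eps 1e-6), ftol 1e-6, at most 160
  iterations.  All inequality rows are scaled to order one; an iterate is
  accepted as feasible below 1e-4 in scaled units.  A best-feasible-
  iterate safeguard returns the cheapest feasible point seen, so a
  predictive solve warm-started from the (feasible) tracking solution can
  never end above it — the optimization-dominance property holds by
  construction whenever the start is feasible.
* Warm-start chain: tracking blocks start from the synthetic reference;
  human-only predictive blocks from the human-only tracking solution;
  exoskeleton predictive blocks from the matching human-only predictive
  technique (zero motor control appended), with the exoskeleton tracking
  solution registered as a fallback bound.  Because the hybrid objective
  is the sum of the other two, the HYB blocks are additionally
  multistarted (deterministically) from the same variant's solved PLBL
  and CLBL techniques and the best feasible solution by its own cost is
  kept.  A final cross-candidate pass re-evaluates every predictive
  block's objective on its siblings' solved techniques and adopts a
  sibling's solution when it is feasible and strictly cheaper — a cheap,
  deterministic guard against one block settling in a worse local basin
  than another found for the same model.

State derivatives at samples are central differences of the composed
spline-to-coordinates map with a 1-ms step; the discretization is exact
to O(h^2) and, crucially, a smooth function of the decision variables, so
finite-difference gradients are noise-free.

## Synthetic reference motion

No public recording of the original experiment exists, so the tracking
target is generated: minimum-jerk interpolation in the reduced
coordinates between a standing keyframe, a grasp keyframe (hip, shoulder
and elbow solved so the hands land exactly on the handle at the
configured 55 deg peak lumbar flexion), and standing again, over phases
of 1.2 / 0.4 / 1.4 s; the posture is held during load transfer while the
hand force ramps smoothly.  Virtual markers (two per major segment) come
from forward kinematics plus seeded Gaussian noise; inverse kinematics
fits the six reduced coordinates per frame by nonlinear least squares,
which enforces the lumbar coupling and planted feet during the fit.

The generator emulates the kinematic structure, phase logic, smoothness
and load-transfer physics of a stoop-squat lift, and its ground
reactions satisfy the impulse balance.  It does not emulate soft-tissue
artifact, force-plate noise, left-right asymmetry, inter-trial
variability, or the participant's exact joint-angle waveforms.  Passing
tests therefore demonstrate that the pipeline recovers and improves upon
a known, physically consistent motion — not that the absolute load
levels of any specific person are reproduced.  The reconstructed
magnitudes (peak L5/S1 moment ~170-180 N m, cumulative load
~260 N m s for the tracked lift) fall in the range reported for
comparable lifts, which is a plausibility check, not a validation.

## Numerical choices and degenerate inputs

* Inverse dynamics is a square linear solve per sample (joint torques +
  multipliers), batched over all samples and phases; the lumbar split
  reduces the torque redundancy to one scalar per sample.
* Singular constraint sets (e.g. duplicated rows) are detected by a
  singular-value check on G and reported with the offending row labels.
* The two-link attachment closure selects the branch keeping the pelvis
  module upright; an unreachable pelvis pin raises immediately.
* Zero-mass subjects, empty moment series, non-summing coupling
  coefficients, missing anthropometric rows, non-positive beam
  separation and under-determined marker sets all raise informative
  errors rather than propagating NaNs.

## Limitations

Muscles, muscle dynamics and co-contraction are not modeled (torque
actuation only), so the load metrics are net-moment surrogates.  The
planar model cannot express asymmetric lifting or axial twist.  The
exoskeleton joint layout and beam-mount geometry are configurable
approximations of the real device, not dimensioned drawings.  SLSQP with
dense finite-difference gradients finds local optima; the deterministic
warm-start chain makes runs reproducible but cannot guarantee global
optimality, and the acceptance properties are asserted for the solutions
it returns.  The printed cumulative/peak load values of the original
participant are not reproducible here because the underlying recordings
are not public; this package reproduces the study *design* on its
synthetic stand-in.
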