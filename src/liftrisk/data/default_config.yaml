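# Default model/study configuration.
#
# Anthropometric fractions follow the adjusted Zatsiorsky/de-Leva male
# segment-inertia tables, regrouped onto the 11 sagittal-plane segments of
# this model (left/right limbs merged, head+neck folded into the torso,
# mid-trunk mass shared between the four free lumbar vertebra bodies and the
# torso).  Fractions are renormalized at load time so segment masses sum to
# the configured total mass exactly.
gravity: 9.81

human:
  height: 1.69          # m
  total_mass: 76.5      # kg
  ankle_height_frac: 0.039   # ankle joint height / stature
  foot_forward_frac: 0.19    # foot CoM forward of ankle / foot length
  # mass_frac: fraction of body mass (merged sides); length_frac: segment
  # length / stature; com_frac: CoM position along segment from proximal
  # joint / length; rgyr_frac: transverse radius of gyration / length.
  segments:
    pelvis:       {mass_frac: 0.1117, length_frac: 0.065, com_frac: 0.50,   rgyr_frac: 0.615}
    thigh:        {mass_frac: 0.2832, length_frac: 0.245, com_frac: 0.4095, rgyr_frac: 0.329}
    shank:        {mass_frac: 0.0866, length_frac: 0.246, com_frac: 0.4459, rgyr_frac: 0.255}
    foot:         {mass_frac: 0.0274, length_frac: 0.152, com_frac: 0.44,   rgyr_frac: 0.257}
    l5:           {mass_frac: 0.0150, length_frac: 0.021, com_frac: 0.50,   rgyr_frac: 0.40}
    l4:           {mass_frac: 0.0150, length_frac: 0.021, com_frac: 0.50,   rgyr_frac: 0.40}
    l3:           {mass_frac: 0.0150, length_frac: 0.021, com_frac: 0.50,   rgyr_frac: 0.40}
    l2:           {mass_frac: 0.0150, length_frac: 0.021, com_frac: 0.50,   rgyr_frac: 0.40}
    torso:        {mass_frac: 0.3323, length_frac: 0.140, com_frac: 0.62,   rgyr_frac: 0.55}
    upper_arm:    {mass_frac: 0.0542, length_frac: 0.186, com_frac: 0.5772, rgyr_frac: 0.285}
    forearm_hand: {mass_frac: 0.0446, length_frac: 0.175, com_frac: 0.57,   rgyr_frac: 0.45}

lumbar:
  # Fraction of total lumbar flexion carried by each joint, ordered from
  # L5/S1 upward to L1/L2; must sum to 1 (in-vivo coordination data).
  coefficients: [0.21, 0.25, 0.22, 0.18, 0.14]
  # Extension offsets (deg) posing the resting lordosis at zero flexion,
  # same joint ordering.
  bias_deg: [15.0, 12.0, 9.0, 6.0, 3.0]
  m_max: 250.0          # N m, normalizing torque per lumbar joint
  baumgarte_2alpha: 10.0   # 1/s, velocity-error gain (2*alpha)
  baumgarte_beta2: 25.0    # 1/s^2, position-error gain (beta^2)

box:
  mass: 10.0            # kg
  width: 0.30           # m
  height: 0.30          # m
  x: 0.42               # m, box centre forward of the ankles
  handle_height_frac: 1.0  # handle height on the box (1.0 = top edge)

exoskeleton:
  total_mass: 9.12      # kg
  # six segments; masses must sum to total_mass
  segment_masses:
    thigh_module: 2.92
    pelvis_module: 3.50
    pelvis_interface: 0.50
    trunk_module: 1.20
    beam_mount: 0.70
    roller_mount: 0.30
  # attachment geometry (m), expressed in the named parent frame
  thigh_weld_offset: [0.05, -0.30]    # thigh frame -> thigh module origin
  exo_hip_local: [0.0, 0.30]          # thigh-module frame -> exo hip joint
  pelvis_pivot_local: [0.0, 0.14]     # pelvis-module frame -> interface pivot
  interface_pin_local: [0.0, 0.08]    # interface frame -> pelvis pin point
  pelvis_pin_human: [-0.10, 0.10]     # human pelvis frame -> pin point
  trunk_weld_offset: [-0.08, 0.18]    # torso frame -> trunk module origin
  beam_mount_local: [-0.13, -0.16]    # pelvis-module frame -> beam root
  roller_local: [0.0, 0.08]           # trunk-module frame -> rollers
  beam:
    youngs_modulus: 166.0e9   # Pa, carbon fiber rods
    diameter: 4.7e-3          # m
    n_rods: 3
  actuator_max_torque: 25.0   # N m, hydraulic hip actuator

risk:
  m_max: [250.0, 250.0, 250.0, 250.0, 250.0]  # N m per lumbar joint
  lsq_tracking_weight: 1.0       # rad^-2
  lsq_exo_weight: 5.0e-2         # on integral of u^2
  torque_reg_weight: 1.0e-3      # Eq-style all-joint regularization weight

ocp:
  friction_mu: 0.8
  interaction_force_limit: 200.0   # N per attachment component
  interaction_moment_limit: 60.0   # N m on weld rows
  hand_moment_limit: 15.0          # N m open-grip moment bound
  phase_duration_bounds: [0.2, 3.0]
  intervals_per_phase: [4, 4, 4]
  smoothness_weight: 5.0e-5   # knot-curvature penalty (motion smoothness)
  torque_limits:   # N m, per joint coordinate group
    hip: 320.0
    knee: 320.0
    ankle: 250.0
    shoulder: 160.0
    elbow: 130.0
  solver:
    maxiter: 160
    ftol: 1.0e-6
    eps: 1.0e-6

scenario:
  phase_durations: [1.2, 0.4, 1.4]   # s (stand->touch, load transfer, lift)
  peak_lumbar_flexion_deg: 55.0
  standing:    # independent coordinates [ankle, knee, hip, lumbar_flexion, shoulder, elbow]
    ankle: 0.0
    knee: 0.0
    hip: 0.0
    shoulder: 0.0
    elbow: 0.0
  grasp:       # initial guess for the grasp-pose closure solve
    ankle: 0.35
    knee: -0.9
    hip: 1.2
    shoulder: 1.4
    elbow: 0.1
  hand_grasp_angle: 0.0   # world hand-frame angle at grasp (rad)
  marker_noise_std: 0.0   # m
  seed: 42
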