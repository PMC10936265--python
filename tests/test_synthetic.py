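"""Synthetic reference generation and marker-based inverse kinematics."""

import numpy as np
import pytest

from liftrisk.synthetic import (
    LiftScenario,
    ReferenceMotion,
    generate_reference,
    inverse_kinematics,
    marker_set,
)


def test_scenario_validation():
    with pytest.raises(ValueError):
        LiftScenario(phase_durations=np.array([1.0, -0.5, 1.0]))


def test_markers_lie_on_model_landmarks_without_noise(ho_model, scenario, ho_motion):
    markers = ho_motion.markers(hz=25)
    traj = ho_motion.sample(hz=25)
    kin = ho_model.model.kinematics(traj.q)
    for mname, body, local in marker_set(ho_model):
        pos, _ = ho_model.model.point_kinematics(kin, body, local)
        assert np.allclose(markers[f"{mname}_x"], pos[:, 0], atol=1e-12)
        assert np.allclose(markers[f"{mname}_z"], pos[:, 1], atol=1e-12)


def test_reference_starts_and_ends_at_rest(ho_motion):
    traj = ho_motion.sample(hz=50)
    assert np.abs(traj.qd[0]).max() < 1e-6
    assert np.abs(traj.qd[-1]).max() < 1e-6


def test_grasp_keyframe_feasible(ho_model, ho_motion):
    """Hands exactly on the handle; box and feet constraints satisfied."""
    q = ho_motion.rmap.q(ho_motion.zeta_grasp, 2)
    res = ho_model.phase_constraints(2).residual(q)
    assert np.abs(res).max() < 1e-8


def test_impulse_balance(ho_motion, ho_model):
    """Momentum theorem: integral of vertical ground force = weight x time."""
    traj = ho_motion.sample(hz=100)
    grf = traj.lam["feet"][:, 1] + traj.lam["box_ground"][:, 1]
    impulse = np.trapezoid(grf, traj.time)
    expected = ho_model.total_mass * ho_model.model.gravity * traj.duration
    assert impulse == pytest.approx(expected, rel=1e-2)


def test_load_transfer_completes_in_phase_two(ho_motion, ho_model):
    traj = ho_motion.sample(hz=50)
    i2 = np.where(traj.phase == 2)[0]
    bg = traj.lam["box_ground"][:, 1]
    # the ramp starts at the phase boundary; the first in-phase sample sits
    # one grid step into it
    assert bg[i2[0]] == pytest.approx(ho_model.box.mass * 9.81, abs=2.0)
    assert abs(bg[i2[-1]]) < 1e-6
    assert bg[i2].min() > -1e-9


def test_ik_recovers_trajectory_without_noise(ho_model, scenario):
    traj, markers, motion = generate_reference(scenario, ho_model, hz=20)
    ik = inverse_kinematics(markers, ho_model)
    zeta_true = motion.rmap.zeta_from_q(traj.q)
    assert not ik.failed_frames
    assert np.sqrt(np.mean((ik.zeta - zeta_true) ** 2)) < 1e-6
    assert np.allclose(ik.q[:, 3:16], traj.q[:, 3:16], atol=1e-5)


def test_ik_joint_error_below_one_degree_with_noise(ho_model, scenario):
    noisy = LiftScenario(
        phase_durations=scenario.phase_durations,
        peak_lumbar_flexion_deg=scenario.peak_lumbar_flexion_deg,
        standing=scenario.standing,
        grasp_guess=scenario.grasp_guess,
        marker_noise_std=2e-3,
        seed=123,
    )
    traj, markers, motion = generate_reference(noisy, ho_model, hz=20)
    ik = inverse_kinematics(markers, ho_model)
    zeta_true = motion.rmap.zeta_from_q(traj.q)
    rms_deg = np.rad2deg(np.sqrt(np.mean((ik.zeta - zeta_true) ** 2)))
    assert rms_deg < 1.0


def test_ik_rejects_underdetermined_marker_set(ho_model, ho_motion):
    markers = ho_motion.markers(hz=10)
    keep = ["time", "pelvis_prox_x", "pelvis_prox_z", "torso_prox_x", "torso_prox_z"]
    with pytest.raises(ValueError, match="not enough marker"):
        inverse_kinematics(markers[keep], ho_model)


def test_marker_noise_is_seeded(ho_model):
    s = LiftScenario(marker_noise_std=1e-3, seed=7)
    m1 = ReferenceMotion(ho_model, s).markers(hz=10)
    m2 = ReferenceMotion(ho_model, s).markers(hz=10)
    assert m1.equals(m2)


def test_generated_reference_feasible_as_ocp_guess(ho_model, ho_motion, cfg):
    """Path constraints hold along the reference (valid initial guess)."""
    traj = ho_motion.sample(hz=50)
    mu = cfg["ocp"]["friction_mu"]
    feet = traj.lam["feet"]
    assert feet[:, 1].min() > 0
    assert np.all(np.abs(feet[:, 0]) <= mu * feet[:, 1] + 1e-9)
    hb = traj.lam["hands_box"]
    m23 = traj.phase >= 2
    assert hb[m23, 1].min() > -1e-9
    assert np.all(np.abs(hb[m23, 0]) <= mu * hb[m23, 1] + 1e-6)
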