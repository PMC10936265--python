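"""OCP transcription structure and guess consistency (no full solves here)."""

import numpy as np
import pytest

from liftrisk.ocp import (
    OCPSpec,
    PhaseSpec,
    TranscribedOCP,
    build_ocp,
    initial_guess_from_reference,
)
from liftrisk.risk import CostSpec


def _spec(cfg, variant, kind, durations):
    return OCPSpec.from_config(cfg, variant, kind, durations)


def test_phase_spec_validation():
    with pytest.raises(ValueError, match="nodes"):
        PhaseSpec(index=1, duration=1.0, fixed_duration=False, n_intervals=3)
    with pytest.raises(ValueError, match="duration"):
        PhaseSpec(index=1, duration=-1.0, fixed_duration=False, n_intervals=4)
    with pytest.raises(ValueError, match="variant"):
        OCPSpec(variant="XX", cost=CostSpec(kind="LSQ"), phases=[])


def test_variant_model_mismatch_rejected(cfg, ho_model, hwe_model, ho_motion):
    with pytest.raises(ValueError, match="exoskeleton"):
        build_ocp(ho_model, _spec(cfg, "HwE", "LSQ", ho_motion.durations), ho_motion)


def test_ho_problem_has_no_exo_controls(cfg, ho_model, hwe_model, ho_motion, hwe_motion):
    ho = build_ocp(ho_model, _spec(cfg, "HO", "CLBL", ho_motion.durations), ho_motion)
    hwe = build_ocp(hwe_model, _spec(cfg, "HwE", "CLBL", hwe_motion.durations), hwe_motion)
    assert not ho.with_exo and hwe.with_exo
    # the exoskeleton problem adds exactly one control channel (K knots)
    assert hwe.n_vars - ho.n_vars == hwe.K
    # and exactly eight extra constraint rows in every phase
    for p in (1, 2, 3):
        assert (
            hwe.lm.phase_constraints(p).n_rows - ho.lm.phase_constraints(p).n_rows == 8
        )


def test_rest_to_rest_boundaries(cfg, ho_model, ho_motion):
    """Knot spline is clamped: zero velocity at start and end by design."""
    ocp = build_ocp(ho_model, _spec(cfg, "HO", "LSQ", ho_motion.durations), ho_motion)
    x0 = initial_guess_from_reference(ocp)
    out = ocp._evaluate(x0)
    assert np.abs(out["qd"][0]).max() < 1e-5
    assert np.abs(out["qd"][-1]).max() < 1e-5


def test_guess_tracks_reference_nearly_exactly(cfg, ho_model, ho_motion):
    """LSQ objective at its own reference is the regularization alone."""
    ocp = build_ocp(ho_model, _spec(cfg, "HO", "LSQ", ho_motion.durations), ho_motion)
    x0 = initial_guess_from_reference(ocp)
    out = ocp._evaluate(x0)
    assert out["J"] < 0.05  # tracking term vanishes at the reference knots
    assert np.isfinite(out["ineq"]).all() and np.isfinite(out["eq"]).all()
    # hand-pose equalities hold exactly at the knot samples of phase 2;
    # midpoint rows carry only the small spline-interpolation wiggle
    hand_eq = out["eq"][:-3].reshape(-1, 3)
    assert np.abs(hand_eq[::2]).max() < 1e-9
    assert np.abs(hand_eq[1::2]).max() < 5e-3


def test_hwe_guess_has_zero_exo_control(cfg, hwe_model, hwe_motion):
    ocp = build_ocp(hwe_model, _spec(cfg, "HwE", "LSQ", hwe_motion.durations), hwe_motion)
    x0 = initial_guess_from_reference(ocp)
    v = ocp.unpack(x0)
    assert np.allclose(v["u"], 0.0)


def test_dynamics_hold_exactly_at_collocation_samples(cfg, hwe_model, hwe_motion):
    """Inverse-dynamics transcription: the constrained equations of motion
    are satisfied to solver precision at every sample."""
    lm = hwe_model
    ocp = build_ocp(lm, _spec(cfg, "HwE", "LSQ", hwe_motion.durations), hwe_motion)
    x0 = initial_guess_from_reference(ocp)
    out = ocp._evaluate(x0)
    res = out["res"]
    q, qd = out["q"], out["qd"]
    cs = ocp._union_cs
    v = ocp.unpack(x0)
    t_knots = ocp._knot_times(v["durations"])
    from scipy.interpolate import CubicSpline

    spline = CubicSpline(t_knots, v["zeta"], bc_type="clamped")
    bounds = t_knots[[0, ocp.i1, ocp.i2, ocp.K - 1]]
    t_s = np.concatenate(
        [np.linspace(bounds[p], bounds[p + 1], ocp.n_per_phase[p]) for p in range(3)]
    )
    for i in (0, 5, 13, 22):
        phase = int(ocp.sample_phase[i])
        t = t_s[i]
        h = 1e-3
        qm = ocp.rmap.q(spline(t), phase)
        qp = ocp.rmap.q(spline(t + h), phase)
        qn = ocp.rmap.q(spline(t - h), phase)
        qdd = (qp - 2 * qm + qn) / h**2
        M = lm.model.mass_matrix(qm)
        hvec = lm.model.bias_forces(qm, (qp - qn) / (2 * h))
        Q = lm.applied_force(qm, res["tau"][i], u=res["u"][i])
        G = cs.jacobian(qm)
        lam_force = np.zeros(lm.nq)
        for name, arr in res["lam"].items():
            lam_force += G[cs.rows_of(name)].T @ arr[i]
        resid = M @ qdd + hvec - Q - lam_force
        assert np.abs(resid).max() < 1e-6


def test_objective_stable_under_node_refinement(cfg, ho_model, ho_motion):
    """Doubling the shooting intervals changes the evaluated objective of
    the reference trajectory by < 1% (quadrature consistency)."""
    import copy

    spec1 = _spec(cfg, "HO", "CLBL", ho_motion.durations)
    cfg2 = copy.deepcopy(cfg)
    cfg2["ocp"]["intervals_per_phase"] = [8, 8, 8]
    spec2 = OCPSpec.from_config(cfg2, "HO", "CLBL", ho_motion.durations)
    o1 = build_ocp(ho_model, spec1, ho_motion)
    o2 = build_ocp(ho_model, spec2, ho_motion)
    J1 = o1.objective(initial_guess_from_reference(o1))
    J2 = o2.objective(initial_guess_from_reference(o2))
    assert abs(J1 - J2) / abs(J2) < 0.01


def test_infeasible_boundary_pose_detected(cfg, ho_model, ho_motion):
    from liftrisk.ocp import check_boundary_poses

    spec = _spec(cfg, "HO", "LSQ", ho_motion.durations)
    ocp = TranscribedOCP(ho_model, spec, ho_motion)
    check_boundary_poses(ocp)  # the genuine reference pose passes
    # a foot hovering above the ground cannot satisfy the feet weld
    ocp.rmap.ankle = ocp.rmap.ankle + np.array([0.0, 0.05])
    with pytest.raises(ValueError, match="boundary pose"):
        check_boundary_poses(ocp)
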