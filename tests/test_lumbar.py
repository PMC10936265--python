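"""Lumbar coupling: constraint rows, flexion angle, torque split."""

import numpy as np
import pytest

from liftrisk.assembly import LUMBAR_COORDS
from liftrisk.lumbar import (
    LumbarCoupling,
    coupling_rows,
    lumbar_constraints,
    lumbar_flexion_angle,
    torque_split,
)


@pytest.fixture(scope="module")
def coupling():
    return LumbarCoupling(
        coefficients=[0.21, 0.25, 0.22, 0.18, 0.14],
        bias_extension_deg=[15.0, 12.0, 9.0, 6.0, 3.0],
    )


def test_coefficients_must_sum_to_one():
    with pytest.raises(ValueError, match="sum"):
        LumbarCoupling([0.3, 0.3, 0.2, 0.1, 0.05], np.zeros(5))
    with pytest.raises(ValueError):
        LumbarCoupling([0.5, 0.5, 0.2, -0.1, -0.1], np.zeros(5))


def test_residuals_zero_at_resting_pose(coupling):
    res, _ = lumbar_constraints(coupling.bias_angles_deg, coupling)
    assert np.allclose(res, 0.0, atol=1e-12)
    assert lumbar_flexion_angle(coupling.bias_angles_deg, coupling) == pytest.approx(0.0)


@pytest.mark.parametrize("theta_l", [40.0, -10.0, 0.0, 55.0])
def test_residuals_zero_on_constraint_manifold(coupling, theta_l):
    q = coupling.coefficients * theta_l + coupling.bias_angles_deg
    res, _ = lumbar_constraints(q, coupling)
    assert np.allclose(res, 0.0, atol=1e-10)
    assert lumbar_flexion_angle(q, coupling) == pytest.approx(theta_l, abs=1e-10)


def test_jacobian_matches_finite_differences(coupling):
    """Oracle: FD of the residual; rows are linear so FD is exact."""
    rng = np.random.default_rng(5)
    q0 = rng.normal(0, 10, 5)
    res0, J = lumbar_constraints(q0, coupling)
    eps = 1e-6
    for j in range(5):
        dq = np.zeros(5)
        dq[j] = eps
        rp, _ = lumbar_constraints(q0 + dq, coupling)
        rm, _ = lumbar_constraints(q0 - dq, coupling)
        fd = (rp - rm) / (2 * eps)
        assert np.allclose(J[:, j], fd, atol=1e-8)
        # only rows touching joint j respond
        touched = np.nonzero(J[:, j])[0]
        assert set(touched) <= {j - 1, j}


def test_nullspace_dimension_is_one(coupling):
    _, J = lumbar_constraints(np.zeros(5), coupling)
    assert np.linalg.matrix_rank(J) == 4  # 5 joints - 4 rows -> 1 sagittal DOF


def test_full_model_coupling_rows(ho_model, ho_rmap):
    """Rows on the assembled model vanish exactly along the reduced map."""
    rows = coupling_rows(LUMBAR_COORDS, ho_model.lumbar_rest, ho_model.lumbar, 16)
    assert len(rows) == 4
    for theta_l in (0.0, 0.7, 1.1):
        zeta = np.array([0.1, -0.4, 0.6, theta_l, 0.3, 0.2])
        q = ho_rmap.q(zeta, 1)
        for r in rows:
            assert abs(r.coeffs @ q - r.offset) < 1e-12


def test_flexion_angle_round_trip_with_generator(ho_motion, ho_rmap, scenario):
    """The generated reference's peak flexion equals the scenario keyframe."""
    traj = ho_motion.sample(hz=50)
    peak = traj.extras["lumbar_flexion_deg"].max()
    assert peak == pytest.approx(scenario.peak_lumbar_flexion_deg, abs=1e-6)


def test_torque_split_is_minimum_norm(coupling):
    """Oracle: brute-force minimization over the constraint line."""
    q_l = 120.0
    tau = torque_split(q_l, coupling)
    assert tau.shape == (5,)
    c = coupling.coefficients
    assert np.dot(c, tau) == pytest.approx(q_l, rel=1e-12)
    # any other admissible split has a larger normalized cost
    rng = np.random.default_rng(9)
    cost = np.sum((tau / coupling.m_max) ** 2)
    for _ in range(50):
        d = rng.normal(0, 5, 5)
        d -= c * np.dot(c, d) / np.dot(c, c)  # stay on the constraint
        alt = tau + d
        assert np.sum((alt / coupling.m_max) ** 2) >= cost - 1e-12
    # all joints participate (no single-joint concentration)
    assert np.all(np.abs(tau) > 0)
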