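"""Exoskeleton beam element, attachments and actuator."""

import numpy as np
import pytest

from liftrisk.dynamics import ConstraintSet
from liftrisk.exoskeleton import (
    BeamSpec,
    actuator_torque,
    attach_exoskeleton,
    beam_end_loads,
    beam_state_from_kinematics,
    fit_beam_spline,
)
from liftrisk.reduced import ReducedMap
from tests.oracles import euler_bernoulli_fem


@pytest.fixture(scope="module")
def beam_spec():
    return BeamSpec()


def test_ei_derived_from_rod_geometry(beam_spec):
    expected = 3 * 166e9 * np.pi * (4.7e-3) ** 4 / 64
    assert beam_spec.EI == pytest.approx(expected, rel=1e-12)
    with pytest.raises(ValueError, match="EI"):
        BeamSpec(EI=2 * expected)


def test_spline_boundary_conditions():
    st = fit_beam_spline(0.3, 0.05)
    s = np.array([0.0, 1.0])
    d = st.deflection(s)
    assert d[0] == pytest.approx(0.0, abs=1e-14)
    assert d[1] == pytest.approx(0.05, rel=1e-12)
    a = st.coeffs
    assert a[1] == pytest.approx(0.0, abs=1e-14)  # delta'(0) = 0
    assert 2 * a[2] + 6 * a[3] == pytest.approx(0.0, abs=1e-12)  # delta''(1) = 0


def test_zero_deflection_gives_zero_polynomial_and_loads(beam_spec):
    st = beam_end_loads(fit_beam_spline(0.3, 0.0), beam_spec)
    assert np.allclose(st.coeffs, 0.0)
    assert np.allclose(st.F_pelvis, 0.0) and np.allclose(st.F_torso, 0.0)
    assert st.M_pelvis == pytest.approx(0.0) and st.M_torso == pytest.approx(0.0)


def test_nonpositive_separation_rejected():
    with pytest.raises(ValueError, match="overlap"):
        fit_beam_spline(0.0, 0.01)


def test_sign_symmetry(beam_spec):
    sp_ = beam_end_loads(fit_beam_spline(0.3, 0.05), beam_spec)
    sm = beam_end_loads(fit_beam_spline(0.3, -0.05), beam_spec)
    assert np.allclose(sp_.F_torso, -sm.F_torso)
    assert sp_.M_pelvis == pytest.approx(-sm.M_pelvis)
    # positive deflection -> restoring force pushes the rollers back
    assert sp_.F_torso[0] < 0


def test_beam_matches_fem_oracle(beam_spec):
    """Spline shape and end loads vs a 100-element discretization, < 1%."""
    L, dL = 0.3, 0.05
    st = beam_end_loads(fit_beam_spline(L, dL), beam_spec)
    s, w, tip_shear, root_moment = euler_bernoulli_fem(L, dL, beam_spec.EI)
    model_w = st.deflection(s)
    assert np.abs(model_w - w).max() <= 0.01 * dL
    P = 3 * beam_spec.EI * dL / L**3
    assert tip_shear == pytest.approx(P, rel=1e-2)
    assert abs(st.F_torso[0]) == pytest.approx(abs(tip_shear), rel=1e-2)
    assert abs(st.M_pelvis) == pytest.approx(abs(root_moment), rel=1e-2)


def test_end_load_equilibrium(beam_spec):
    """Net force and net moment of the two end loads vanish to 1e-9."""
    for L, dL in ((0.3, 0.05), (0.45, 0.12), (0.5, -0.08)):
        st = beam_end_loads(fit_beam_spline(L, dL), beam_spec)
        net_f = st.F_pelvis + st.F_torso
        assert np.abs(net_f).max() < 1e-9
        # moment about the mount: M_pelvis + L z-hat x F_torso
        net_m = st.M_pelvis + (0.0 * st.F_torso[1] - L * st.F_torso[0])
        assert abs(net_m) < 1e-9


def test_deflection_validity_warning(beam_spec, caplog):
    import logging

    logging.getLogger("liftrisk.exoskeleton").setLevel(logging.WARNING)
    with caplog.at_level("WARNING", logger="liftrisk.exoskeleton"):
        fit_beam_spline(0.3, 0.2)
    assert any("validity" in r.message for r in caplog.records)
    logging.getLogger("liftrisk.exoskeleton").setLevel(logging.ERROR)


def test_attachment_rows_total_eight(hwe_model):
    items = attach_exoskeleton(hwe_model.model, hwe_model.exo)
    assert sum(it.rows for it in items) == 8
    cs = ConstraintSet(hwe_model.model, items)
    assert cs.n_rows == 8


def test_attachment_residuals_zero_at_closure(hwe_model):
    rmap = ReducedMap(hwe_model)
    cs = ConstraintSet(hwe_model.model, attach_exoskeleton(hwe_model.model, hwe_model.exo))
    for zeta in (np.zeros(6), np.array([0.3, -0.8, 1.1, 0.9, 1.5, -0.1])):
        q = rmap.q(zeta, 1)
        assert np.abs(cs.residual(q)).max() < 1e-9


def test_attachment_residual_reproduces_base_offset(hwe_model):
    """FK oracle: translating the exo base shifts the weld residual equally."""
    rmap = ReducedMap(hwe_model)
    cs = ConstraintSet(hwe_model.model, attach_exoskeleton(hwe_model.model, hwe_model.exo))
    q = rmap.q(np.zeros(6), 1)
    offset = np.array([0.013, -0.007])
    q2 = q.copy()
    q2[16:18] += offset  # thigh-module base translation
    res = cs.residual(q2)
    assert np.allclose(res[cs.rows_of("exo_thigh")][:2], offset, atol=1e-12)


def test_missing_attachment_frame_raises(ho_model, hwe_model):
    with pytest.raises(ValueError, match="attach"):
        attach_exoskeleton(ho_model.model, hwe_model.exo)


@pytest.mark.parametrize("u,expected", [(0.0, 0.0), (1.0, 25.0), (-0.5, -12.5)])
def test_actuator_torque_linear(u, expected):
    assert actuator_torque(u) == pytest.approx(expected)


def test_beam_state_from_pose_is_batched(hwe_model):
    rmap = ReducedMap(hwe_model)
    zeta = np.stack([np.zeros(6), np.array([0.3, -0.8, 1.1, 0.9, 1.5, -0.1])])
    kin = hwe_model.model.kinematics(rmap.q(zeta, 1))
    st = beam_state_from_kinematics(hwe_model.model, kin, hwe_model.exo)
    assert st.L.shape == (2,)
    assert np.all(st.L > 0)
    # deep flexion deflects the beam much more than standing
    assert abs(st.deltaL[1]) > abs(st.deltaL[0])
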