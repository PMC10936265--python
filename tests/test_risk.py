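"""CLBL/PLBL analysis metrics and optimization integrands."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from liftrisk.risk import (
    CostSpec,
    RiskNormalization,
    clbl_analysis,
    clbl_cost_integrand,
    hyb_cost_integrand,
    lsq_objective,
    plbl_analysis,
    plbl_cost_integrand,
    torque_regularization,
)

NORM = RiskNormalization()


def test_clbl_constant_signal():
    t = np.linspace(0, 2, 101)
    assert clbl_analysis(t, np.full_like(t, 100.0)) == pytest.approx(200.0)
    assert clbl_analysis(t, np.zeros_like(t)) == pytest.approx(0.0)


def test_clbl_is_signed():
    """Analysis integral keeps the sign; a flexion phase reduces it."""
    t = np.linspace(0, 2, 201)
    m = np.where(t < 1, 100.0, -50.0)
    assert clbl_analysis(t, m) == pytest.approx(100 - 50, abs=1.0)
    # the optimization integrand has no such loophole (even in tau)
    assert clbl_cost_integrand(np.full(5, -100.0), NORM) == clbl_cost_integrand(
        np.full(5, 100.0), NORM
    )


def test_plbl_max():
    m = np.zeros(50)
    m[20] = 210.0
    assert plbl_analysis(m) == pytest.approx(210.0)
    assert plbl_analysis(np.full(10, 100.0)) == pytest.approx(100.0)


def test_empty_series_rejected():
    with pytest.raises(ValueError):
        clbl_analysis(np.array([]), np.array([]))
    with pytest.raises(ValueError):
        plbl_analysis(np.array([]))


@pytest.mark.parametrize(
    "fn,at_mmax,scale4",
    [
        (clbl_cost_integrand, 5.0, 4.0),
        (plbl_cost_integrand, 5.0, 16.0),
        (hyb_cost_integrand, 10.0, None),
    ],
)
def test_integrand_reference_values(fn, at_mmax, scale4):
    assert fn(np.zeros(5), NORM) == pytest.approx(0.0)
    assert fn(NORM.m_max.copy(), NORM) == pytest.approx(at_mmax)
    if scale4 is not None:
        tau = np.array([50.0, 80.0, 60.0, 40.0, 30.0])
        assert fn(2 * tau, NORM) == pytest.approx(scale4 * fn(tau, NORM), rel=1e-12)


def test_hyb_below_twice_clbl_inside_unit_ball():
    tau = np.array([100.0, 200.0, 150.0, 80.0, 50.0])  # all below M_max
    assert hyb_cost_integrand(tau, NORM) < 2 * clbl_cost_integrand(tau, NORM)


@given(
    k=st.floats(min_value=1.0, max_value=10.0),
    seed=st.integers(min_value=0, max_value=2**16),
)
@settings(max_examples=25, deadline=None)
def test_scaling_monotonicity(k, seed):
    """CLBL/PLBL scale by k; quadratic by k^2; quartic by k^4."""
    rng = np.random.default_rng(seed)
    t = np.linspace(0, 2.5, 64)
    m = 50 + 30 * np.sin(2 * np.pi * t / 2.5) + rng.normal(0, 5, t.size)
    tau = rng.uniform(10, 120, 5)
    assert clbl_analysis(t, k * m) == pytest.approx(k * clbl_analysis(t, m), rel=1e-9)
    assert plbl_analysis(k * m) == pytest.approx(k * plbl_analysis(m), rel=1e-9)
    assert clbl_cost_integrand(k * tau, NORM) == pytest.approx(
        k**2 * clbl_cost_integrand(tau, NORM), rel=1e-9
    )
    assert plbl_cost_integrand(k * tau, NORM) == pytest.approx(
        k**4 * plbl_cost_integrand(tau, NORM), rel=1e-9
    )


def test_quadrature_refinement_below_tenth_percent():
    f = lambda t: 120 + 80 * np.sin(1.3 * t) * np.exp(-0.2 * t)
    t1 = np.linspace(0, 3, 151)
    t2 = np.linspace(0, 3, 301)
    c1 = clbl_analysis(t1, f(t1))
    c2 = clbl_analysis(t2, f(t2))
    assert abs(c2 - c1) / abs(c2) < 1e-3


def test_normalization_validation():
    with pytest.raises(ValueError):
        RiskNormalization(m_max=np.array([250, 250, 0, 250, 250]))
    with pytest.raises(ValueError):
        CostSpec(kind="nope")


def test_lsq_objective_quadratic_structure():
    rng = np.random.default_rng(1)
    q_ref = rng.normal(0, 1, (11, 13))
    t = np.linspace(0, 3, 11)
    assert lsq_objective(q_ref, q_ref) == pytest.approx(0.0)
    # perfect tracking with exo control only
    u = 0.5 * np.ones(11)
    J = lsq_objective(q_ref, q_ref, u_nodes=u, node_times=t, exo_weight=0.1)
    assert J == pytest.approx(0.1 * 0.25 * 3.0)
    # offsetting one coordinate at one node raises the cost by w * eps^2
    eps = 0.01
    q2 = q_ref.copy()
    q2[4, 7] += eps
    assert lsq_objective(q2, q_ref, tracking_weight=2.0) == pytest.approx(
        2.0 * eps**2
    )
    with pytest.raises(ValueError, match="mismatch"):
        lsq_objective(q_ref[:5], q_ref)


def test_torque_regularization_scale():
    tau = np.array([100.0, 50.0])
    lim = np.array([200.0, 100.0])
    assert torque_regularization(tau, lim, weight=1e-3) == pytest.approx(5e-4)
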