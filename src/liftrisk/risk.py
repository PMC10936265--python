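"""Low-back load risk metrics and optimization cost integrands.

Two deliberately distinct code paths:

* analysis metrics, used for reporting: CLBL is the time integral of the
  signed, extension-positive L5/S1 intersegmental moment (N m s) and PLBL
  its maximum (N m);
* optimization integrands, used inside the optimal control problems: the
  sum over the five coupled lumbar joints of the normalized torque raised
  to the power 2 (cumulative-load surrogate), 4 (peak-load surrogate,
  penalizing peaks harder), or their sum (hybrid).  The integrands are
  even in the torque, which removes the sign loophole of the analysis
  integral (a flexion torque must not "pay back" cumulative load).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

N_LUMBAR = 5


@dataclass
class RiskNormalization:
    """Maximum torque output per lumbar joint, used for normalization."""

    m_max: np.ndarray = field(default_factory=lambda: np.full(N_LUMBAR, 250.0))

    def __post_init__(self) -> None:
        self.m_max = np.broadcast_to(
            np.asarray(self.m_max, dtype=float), (N_LUMBAR,)
        ).copy()
        if np.any(self.m_max <= 0):
            raise ValueError("M_max must be positive for all lumbar joints")


@dataclass
class CostSpec:
    """Objective selection and weights for one optimal control problem."""

    kind: str  # LSQ | CLBL | PLBL | HYB
    tracking_weight: float = 1.0
    exo_weight: float = 5.0e-2
    reg_weight: float = 1.0e-3
    normalization: RiskNormalization = field(default_factory=RiskNormalization)

    KINDS = ("LSQ", "CLBL", "PLBL", "HYB")

    def __post_init__(self) -> None:
        if self.kind not in self.KINDS:
            raise ValueError(f"cost kind must be one of {self.KINDS}")
        if min(self.tracking_weight, self.exo_weight, self.reg_weight) < 0:
            raise ValueError("cost weights must be >= 0")


# -- analysis metrics ---------------------------------------------------


def _check_series(time: np.ndarray, moment: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    time = np.asarray(time, dtype=float)
    moment = np.asarray(moment, dtype=float)
    if time.size == 0 or moment.size == 0:
        raise ValueError("empty L5/S1 moment series")
    if time.shape != moment.shape:
        raise ValueError("time and moment series must have matching shapes")
    return time, moment


def clbl_analysis(time: np.ndarray, l5s1_moment: np.ndarray) -> float:
    """Cumulative low-back load: integral of the signed moment, N m s."""
    time, moment = _check_series(time, l5s1_moment)
    return float(np.trapezoid(moment, time))


def plbl_analysis(l5s1_moment: np.ndarray, time: np.ndarray | None = None) -> float:
    """Peak low-back load: maximum extension moment over the motion, N m."""
    if time is not None:
        _check_series(time, l5s1_moment)
    moment = np.asarray(l5s1_moment, dtype=float)
    if moment.size == 0:
        raise ValueError("empty L5/S1 moment series")
    return float(moment.max())


# -- optimization integrands -------------------------------------------


def _normalized(lumbar_torques: np.ndarray, norm: RiskNormalization) -> np.ndarray:
    lt = np.asarray(lumbar_torques, dtype=float)
    if lt.shape[-1] != N_LUMBAR:
        raise ValueError("expected torques for the five lumbar joints")
    return lt / norm.m_max


def clbl_cost_integrand(
    lumbar_torques: np.ndarray, norm: RiskNormalization
) -> np.ndarray:
    """Sum over joints of the squared normalized lumbar torque."""
    r = _normalized(lumbar_torques, norm)
    return np.sum(r**2, axis=-1)


def plbl_cost_integrand(
    lumbar_torques: np.ndarray, norm: RiskNormalization
) -> np.ndarray:
    """Sum over joints of the normalized lumbar torque to the fourth power."""
    r = _normalized(lumbar_torques, norm)
    return np.sum(r**4, axis=-1)


def hyb_cost_integrand(
    lumbar_torques: np.ndarray, norm: RiskNormalization
) -> np.ndarray:
    """Hybrid integrand: quadratic plus quartic terms."""
    return clbl_cost_integrand(lumbar_torques, norm) + plbl_cost_integrand(
        lumbar_torques, norm
    )


def torque_regularization(
    torques: np.ndarray, limits: np.ndarray, weight: float
) -> np.ndarray:
    """Small all-joint regularization rate, w * sum((tau/limit)^2)."""
    t = np.asarray(torques, dtype=float) / np.asarray(limits, dtype=float)
    return weight * np.sum(t**2, axis=-1)


def lsq_objective(
    q_nodes: np.ndarray,
    q_ref: np.ndarray,
    tracking_weight: float = 1.0,
    u_nodes: np.ndarray | None = None,
    node_times: np.ndarray | None = None,
    exo_weight: float = 0.0,
    reg_rate: np.ndarray | None = None,
) -> float:
    """Least-squares tracking objective.

    Sum over shooting nodes of the weighted squared deviation of the
    positional coordinates from the reference, plus (when an exoskeleton
    control trajectory is given) the time integral of the squared motor
    control, plus an optional integrated regularization rate.
    """
    q_nodes = np.asarray(q_nodes, dtype=float)
    q_ref = np.asarray(q_ref, dtype=float)
    if q_nodes.shape != q_ref.shape:
        raise ValueError(
            f"trajectory/reference shape mismatch: {q_nodes.shape} vs {q_ref.shape}"
        )
    J = tracking_weight * float(np.sum((q_nodes - q_ref) ** 2))
    if u_nodes is not None:
        if node_times is None:
            raise ValueError("node_times required to integrate the exo control")
        J += exo_weight * float(np.trapezoid(np.asarray(u_nodes) ** 2, node_times))
    if reg_rate is not None:
        if node_times is None:
            raise ValueError("node_times required to integrate the regularization")
        J += float(np.trapezoid(np.asarray(reg_rate), node_times))
    return J
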