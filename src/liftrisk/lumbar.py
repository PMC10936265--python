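"""Coupled lumbar spine kinematics.

The lumbar spine is articulated as five sagittal revolute joints (L5/S1 up
to L1/L2) whose flexion angles are slaved to the total lumbar flexion
angle theta_L: joint i carries the fraction c_i of theta_L, with
sum(c_i) = 1.  Four linear constraint rows between neighbouring joints
leave the chain a single sagittal degree of freedom.  Each joint angle is
offset by a bias so that theta_L = 0 reproduces the resting lordosis
(biases are configured as degrees of extension).

Functions here work in flexion-positive joint angles; the sign map to the
model's counter-clockwise generalized coordinates is handled by the
assembler, which builds the (sign-invariant) linear coupling rows.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dynamics import LinearCoupling

N_JOINTS = 5
N_CONSTRAINTS = 4


@dataclass
class LumbarCoupling:
    """Flexion-sharing coefficients and resting biases of the lumbar joints.

    coefficients : fraction of total lumbar flexion per joint, L5/S1 upward.
    bias_extension_deg : extension offset of each joint at zero flexion.
    """

    coefficients: np.ndarray
    bias_extension_deg: np.ndarray
    m_max: np.ndarray | float = 250.0

    def __post_init__(self) -> None:
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        self.bias_extension_deg = np.asarray(self.bias_extension_deg, dtype=float)
        self.m_max = np.broadcast_to(np.asarray(self.m_max, float), (N_JOINTS,)).copy()
        if self.coefficients.shape != (N_JOINTS,):
            raise ValueError("need five lumbar coupling coefficients")
        if np.any(self.coefficients <= 0):
            raise ValueError("lumbar coupling coefficients must be positive")
        if abs(self.coefficients.sum() - 1.0) > 1e-6:
            raise ValueError(
                f"lumbar coupling coefficients sum to {self.coefficients.sum()}, expected 1"
            )
        if np.any(self.m_max <= 0):
            raise ValueError("lumbar M_max must be positive")

    @property
    def bias_angles_deg(self) -> np.ndarray:
        """Resting joint angles in flexion-positive degrees (extension < 0)."""
        return -self.bias_extension_deg

    @classmethod
    def from_config(cls, cfg: dict) -> "LumbarCoupling":
        lc = cfg["lumbar"]
        return cls(
            coefficients=lc["coefficients"],
            bias_extension_deg=lc["bias_deg"],
            m_max=lc.get("m_max", 250.0),
        )


def lumbar_constraints(
    q_lumbar: np.ndarray, coupling: LumbarCoupling
) -> tuple[np.ndarray, np.ndarray]:
    """Residuals and Jacobian of the four coupling rows.

    ``q_lumbar`` holds the five flexion-positive lumbar joint angles in
    degrees or radians (rows are homogeneous, so units only need to match
    the bias angles -- degrees here).  On the constraint manifold each
    debiased angle is c_i * theta_L, so neighbouring pairs satisfy
    c_{i+1} (q_i - b_i) - c_i (q_{i+1} - b_{i+1}) = 0.

    Returns (residual (..., 4), jacobian (4, 5)); the Jacobian is constant.
    """
    q_lumbar = np.asarray(q_lumbar, dtype=float)
    if q_lumbar.shape[-1] != N_JOINTS:
        raise ValueError("expected five lumbar joint coordinates")
    c = coupling.coefficients
    b = coupling.bias_angles_deg
    J = np.zeros((N_CONSTRAINTS, N_JOINTS))
    res = np.zeros(q_lumbar.shape[:-1] + (N_CONSTRAINTS,))
    for k in range(N_CONSTRAINTS):
        J[k, k] = c[k + 1]
        J[k, k + 1] = -c[k]
        res[..., k] = c[k + 1] * (q_lumbar[..., k] - b[k]) - c[k] * (
            q_lumbar[..., k + 1] - b[k + 1]
        )
    return res, J


def lumbar_flexion_angle(q_lumbar: np.ndarray, coupling: LumbarCoupling) -> np.ndarray:
    """Total lumbar flexion theta_L = sum(q_i - bias_i), flexion-positive."""
    q_lumbar = np.asarray(q_lumbar, dtype=float)
    if q_lumbar.shape[-1] != N_JOINTS:
        raise ValueError("expected five lumbar joint coordinates")
    return (q_lumbar - coupling.bias_angles_deg).sum(axis=-1)


def coupling_rows(
    coord_indices: np.ndarray, rest_coords: np.ndarray, coupling: LumbarCoupling, nq: int
) -> list[LinearCoupling]:
    """The four coupling rows on the full generalized-coordinate vector.

    ``rest_coords`` are the model's lumbar coordinates at zero flexion in
    the model's own sign convention; the rows are sign-invariant.
    """
    c = coupling.coefficients
    rows = []
    for k in range(N_CONSTRAINTS):
        a = np.zeros(nq)
        a[coord_indices[k]] = c[k + 1]
        a[coord_indices[k + 1]] = -c[k]
        offset = c[k + 1] * rest_coords[k] - c[k] * rest_coords[k + 1]
        rows.append(LinearCoupling(f"lumbar:{k}", a, offset))
    return rows


def torque_split(q_l_net: np.ndarray, coupling: LumbarCoupling) -> np.ndarray:
    """Distribute the net lumbar generalized force over the five joints.

    Only sum(c_i tau_i) is determined by the coupled dynamics; among all
    valid splits we take the one minimizing sum((tau_i / M_max_i)^2),
    which is tau_i = c_i M_i^2 / sum(c_j^2 M_j^2) * Q_L -- the split the
    torque-regularized optimal control converges to.
    """
    c, m2 = coupling.coefficients, coupling.m_max**2
    d = c * m2 / np.sum(c**2 * m2)
    return np.multiply.outer(np.asarray(q_l_net, dtype=float), d)
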