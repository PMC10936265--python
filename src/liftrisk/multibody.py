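"""Planar rigid-multibody kinematics and dynamics.

Bodies live in the sagittal (x, z) plane: x points forward, z up, and
rotations are measured counter-clockwise in that plane (a hanging segment
tips forward for positive angle).  Models are kinematic trees whose joints
are either 3-DOF planar free joints (floating bases), 1-DOF revolutes, or
0-DOF fixed mounts.  All kinematic quantities are evaluated in batch: any
leading array shape on ``q`` broadcasts through.

The dynamics contract is the standard constrained form

    M(q) qdd + h(q, qd) = Q + G(q)^T lam,

where ``h`` collects Coriolis, centripetal and gravity terms.  ``M`` and
``h`` are assembled from body Jacobians; constraint handling lives in
:mod:`liftrisk.dynamics`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

FREE = "free"
REVOLUTE = "revolute"
FIXED = "fixed"

_JOINT_NQ = {FREE: 3, REVOLUTE: 1, FIXED: 0}


def rot(theta: np.ndarray) -> np.ndarray:
    """Planar rotation matrices, shape (..., 2, 2)."""
    c, s = np.cos(theta), np.sin(theta)
    return np.stack(
        [np.stack([c, -s], axis=-1), np.stack([s, c], axis=-1)], axis=-2
    )


def apply_rot(theta: np.ndarray, v: np.ndarray) -> np.ndarray:
    """R(theta) @ v for broadcast theta (...,) and v (..., 2)."""
    c, s = np.cos(theta), np.sin(theta)
    x, z = v[..., 0], v[..., 1]
    out = np.empty(np.broadcast_shapes(np.shape(c), np.shape(x)) + (2,))
    out[..., 0] = c * x - s * z
    out[..., 1] = s * x + c * z
    return out


def perp(v: np.ndarray) -> np.ndarray:
    """d/dtheta R(theta) v = perp(R v); rotates a vector by +90 degrees."""
    out = np.empty_like(v)
    out[..., 0] = -v[..., 1]
    out[..., 1] = v[..., 0]
    return out


@dataclass
class Body:
    """One rigid segment of the tree.

    ``anchor`` is the joint location in the parent frame (for ``free``
    joints it is a world offset).  ``com`` is the centre of mass in the
    body frame, whose origin sits at the joint.
    """

    name: str
    joint_type: str
    parent: int  # index into model.bodies, -1 for world
    anchor: np.ndarray
    mass: float
    com: np.ndarray
    inertia: float  # about the CoM, kg m^2
    angle_offset: float = 0.0

    def __post_init__(self) -> None:
        self.anchor = np.asarray(self.anchor, dtype=float)
        self.com = np.asarray(self.com, dtype=float)
        if self.joint_type not in _JOINT_NQ:
            raise ValueError(f"unknown joint type {self.joint_type!r}")
        if self.mass < 0 or self.inertia < 0:
            raise ValueError(f"body {self.name}: negative mass/inertia")


@dataclass
class FrameKinematics:
    """Batched frame poses and their coordinate Jacobians."""

    theta: np.ndarray  # (...,)
    pos: np.ndarray  # (..., 2) frame origin
    jtheta: np.ndarray  # (..., nq)
    jpos: np.ndarray  # (..., 2, nq)


@dataclass
class FrameRates:
    """Batched frame velocities and zero-qdd acceleration bias terms."""

    omega: np.ndarray  # (...,)
    vel: np.ndarray  # (..., 2)
    alpha0: np.ndarray  # (...,) angular acceleration with qdd = 0
    acc0: np.ndarray  # (..., 2) origin acceleration with qdd = 0


class MultibodyModel:
    """A kinematic tree of planar bodies with generalized coordinates."""

    def __init__(self, bodies: list[Body], gravity: float = 9.81):
        self.bodies = list(bodies)
        self.gravity = float(gravity)
        self._index = {b.name: i for i, b in enumerate(self.bodies)}
        if len(self._index) != len(self.bodies):
            raise ValueError("duplicate body names")
        self.coord_slices: list[slice] = []
        n = 0
        for b in self.bodies:
            if b.parent >= len(self.bodies):
                raise ValueError(f"body {b.name}: parent index out of range")
            k = _JOINT_NQ[b.joint_type]
            self.coord_slices.append(slice(n, n + k))
            n += k
        self.nq = n

    # -- structure ---------------------------------------------------

    def body_index(self, name: str) -> int:
        try:
            return self._index[name]
        except KeyError:
            raise KeyError(
                f"no body named {name!r}; have {sorted(self._index)}"
            ) from None

    @property
    def total_mass(self) -> float:
        return float(sum(b.mass for b in self.bodies))

    def coord_index(self, name: str) -> int:
        """First generalized-coordinate index of the named body's joint."""
        i = self.body_index(name)
        sl = self.coord_slices[i]
        if sl.start == sl.stop:
            raise ValueError(f"body {name!r} has a fixed joint (no coordinate)")
        return sl.start

    # -- kinematics --------------------------------------------------

    def kinematics(self, q: np.ndarray) -> list[FrameKinematics]:
        """Frame poses and Jacobians for every body; q shape (..., nq)."""
        q = np.asarray(q, dtype=float)
        batch = q.shape[:-1]
        nq = self.nq
        out: list[FrameKinematics] = []
        zero_th = np.zeros(batch)
        zero_pos = np.zeros(batch + (2,))
        zero_jt = np.zeros(batch + (nq,))
        zero_jp = np.zeros(batch + (2, nq))
        for i, b in enumerate(self.bodies):
            if b.parent < 0:
                th_p, r_p = zero_th, zero_pos
                jt_p, jp_p = zero_jt, zero_jp
            else:
                p = out[b.parent]
                th_p, r_p, jt_p, jp_p = p.theta, p.pos, p.jtheta, p.jpos
            sl = self.coord_slices[i]
            if b.joint_type == FREE:
                theta = q[..., sl.start + 2] + b.angle_offset
                pos = b.anchor + q[..., sl.start : sl.start + 2]
                jt = zero_jt.copy()
                jt[..., sl.start + 2] = 1.0
                jp = zero_jp.copy()
                jp[..., 0, sl.start] = 1.0
                jp[..., 1, sl.start + 1] = 1.0
            else:
                ra = apply_rot(th_p, b.anchor)
                pos = r_p + ra
                jp = jp_p + perp(ra)[..., :, None] * jt_p[..., None, :]
                if b.joint_type == REVOLUTE:
                    theta = th_p + q[..., sl.start] + b.angle_offset
                    jt = jt_p.copy()
                    jt[..., sl.start] += 1.0
                else:  # fixed
                    theta = th_p + b.angle_offset
                    jt = jt_p
            out.append(FrameKinematics(theta, pos, jt, jp))
        return out

    def rates(
        self, q: np.ndarray, qd: np.ndarray, kin: list[FrameKinematics] | None = None
    ) -> list[FrameRates]:
        """Frame velocities plus the qdd = 0 acceleration bias terms."""
        q = np.asarray(q, dtype=float)
        qd = np.asarray(qd, dtype=float)
        if kin is None:
            kin = self.kinematics(q)
        batch = q.shape[:-1]
        zero = np.zeros(batch)
        zero2 = np.zeros(batch + (2,))
        out: list[FrameRates] = []
        for i, b in enumerate(self.bodies):
            if b.parent < 0:
                om_p, v_p, al_p, a_p = zero, zero2, zero, zero2
                th_p = zero
            else:
                p = out[b.parent]
                om_p, v_p, al_p, a_p = p.omega, p.vel, p.alpha0, p.acc0
                th_p = kin[b.parent].theta
            sl = self.coord_slices[i]
            if b.joint_type == FREE:
                omega = qd[..., sl.start + 2]
                vel = qd[..., sl.start : sl.start + 2]
                alpha0, acc0 = zero, zero2
            else:
                ra = apply_rot(th_p, b.anchor)
                vel = v_p + om_p[..., None] * perp(ra)
                acc0 = (
                    a_p
                    + al_p[..., None] * perp(ra)
                    - (om_p**2)[..., None] * ra
                )
                if b.joint_type == REVOLUTE:
                    omega = om_p + qd[..., sl.start]
                else:
                    omega = om_p
                alpha0 = al_p
            out.append(FrameRates(omega, vel, alpha0, acc0))
        return out

    # -- points ------------------------------------------------------

    def point_kinematics(
        self, kin: list[FrameKinematics], body: int, local: np.ndarray
    ) -> tuple[np.ndarray, np.ndarray]:
        """World position (..., 2) and Jacobian (..., 2, nq) of a body point."""
        f = kin[body]
        rc = apply_rot(f.theta, np.asarray(local, dtype=float))
        pos = f.pos + rc
        jac = f.jpos + perp(rc)[..., :, None] * f.jtheta[..., None, :]
        return pos, jac

    def point_rates(
        self,
        kin: list[FrameKinematics],
        rates: list[FrameRates],
        body: int,
        local: np.ndarray,
    ) -> tuple[np.ndarray, np.ndarray]:
        """World velocity and qdd = 0 acceleration of a body point."""
        f, r = kin[body], rates[body]
        rc = apply_rot(f.theta, np.asarray(local, dtype=float))
        vel = r.vel + r.omega[..., None] * perp(rc)
        acc0 = (
            r.acc0
            + r.alpha0[..., None] * perp(rc)
            - (r.omega**2)[..., None] * rc
        )
        return vel, acc0

    # -- dynamics ----------------------------------------------------

    def mass_matrix(
        self, q: np.ndarray, kin: list[FrameKinematics] | None = None
    ) -> np.ndarray:
        """Joint-space mass matrix, (..., nq, nq); symmetric PD for sane trees."""
        q = np.asarray(q, dtype=float)
        if kin is None:
            kin = self.kinematics(q)
        M = np.zeros(q.shape[:-1] + (self.nq, self.nq))
        for i, b in enumerate(self.bodies):
            if b.mass == 0.0 and b.inertia == 0.0:
                continue
            f = kin[i]
            rc = apply_rot(f.theta, b.com)
            jcom = f.jpos + perp(rc)[..., :, None] * f.jtheta[..., None, :]
            M += b.mass * np.einsum("...ki,...kj->...ij", jcom, jcom)
            M += b.inertia * np.einsum("...i,...j->...ij", f.jtheta, f.jtheta)
        return M

    def bias_forces(
        self,
        q: np.ndarray,
        qd: np.ndarray,
        kin: list[FrameKinematics] | None = None,
        rates: list[FrameRates] | None = None,
    ) -> np.ndarray:
        """h(q, qd) = C(q, qd) qd + g(q), shape (..., nq)."""
        q = np.asarray(q, dtype=float)
        if kin is None:
            kin = self.kinematics(q)
        if rates is None:
            rates = self.rates(q, qd, kin)
        g_acc = np.array([0.0, -self.gravity])
        h = np.zeros(q.shape[:-1] + (self.nq,))
        for i, b in enumerate(self.bodies):
            if b.mass == 0.0 and b.inertia == 0.0:
                continue
            f, r = kin[i], rates[i]
            rc = apply_rot(f.theta, b.com)
            jcom = f.jpos + perp(rc)[..., :, None] * f.jtheta[..., None, :]
            a_com0 = (
                r.acc0
                + r.alpha0[..., None] * perp(rc)
                - (r.omega**2)[..., None] * rc
            )
            h += b.mass * np.einsum("...ki,...k->...i", jcom, a_com0 - g_acc)
            h += b.inertia * r.alpha0[..., None] * f.jtheta
        return h

    def energy(self, q: np.ndarray, qd: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Kinetic and potential energy (batched)."""
        q = np.asarray(q, dtype=float)
        qd = np.asarray(qd, dtype=float)
        kin = self.kinematics(q)
        rates = self.rates(q, qd, kin)
        ke = np.zeros(q.shape[:-1])
        pe = np.zeros(q.shape[:-1])
        for i, b in enumerate(self.bodies):
            f, r = kin[i], rates[i]
            rc = apply_rot(f.theta, b.com)
            v_com = r.vel + r.omega[..., None] * perp(rc)
            ke += 0.5 * b.mass * np.einsum("...k,...k->...", v_com, v_com)
            ke += 0.5 * b.inertia * r.omega**2
            pe += b.mass * self.gravity * (f.pos + rc)[..., 1]
        return ke, pe

    def com(self, q: np.ndarray) -> np.ndarray:
        """Whole-system centre of mass, (..., 2)."""
        kin = self.kinematics(np.asarray(q, dtype=float))
        m = self.total_mass
        acc = np.zeros(np.asarray(q).shape[:-1] + (2,))
        for i, b in enumerate(self.bodies):
            rc = apply_rot(kin[i].theta, b.com)
            acc += b.mass * (kin[i].pos + rc)
        return acc / m
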