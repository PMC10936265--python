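"""Closed-form reduced kinematics of the lifting system.

With the feet welded to the ground and the lumbar joints coupled, the
human model retains six independent coordinates

    zeta = [ankle, knee, hip, lumbar_flexion, shoulder, elbow]

(joint angles in radians; ``lumbar_flexion`` is the flexion-positive total
lumbar angle theta_L).  This module maps zeta to the full generalized
coordinate vector: pelvis base pose by rooting the chain at the planted
foot, lumbar coordinates by the coupling law, the box pose from its
ground rest pose (phases 1-2) or the hand frame (phase 3), and the
exoskeleton coordinates from the attachment closure (weld offsets plus a
closed-form two-link solve for the exo hip and interface pin angles).

All maps broadcast over leading batch dimensions and satisfy the active
constraints exactly, which is what makes the inverse-dynamics OCP
transcription well-posed.
"""

from __future__ import annotations

from typing import TYPE_CHECKING

import numpy as np

from .multibody import apply_rot

if TYPE_CHECKING:
    from .assembly import LiftingModel

N_ZETA = 6
ZETA_NAMES = ("ankle", "knee", "hip", "lumbar_flexion", "shoulder", "elbow")


def two_link_closure(
    root: np.ndarray,
    target: np.ndarray,
    link1_local: np.ndarray,
    link2_local: np.ndarray,
    branch: float = -1.0,
) -> tuple[np.ndarray, np.ndarray]:
    """World angles of a planar two-link chain reaching a target point.

    The first link's frame sits at ``root`` and carries the second link's
    pivot at ``link1_local``; the second link carries the end point at
    ``link2_local``.  Returns the world angles (theta1, theta2) such that
    the end point lands on ``target``; ``branch`` selects the elbow side.
    """
    l1 = float(np.hypot(*np.asarray(link1_local, float)))
    l2 = float(np.hypot(*np.asarray(link2_local, float)))
    a1 = float(np.arctan2(link1_local[1], link1_local[0]))
    a2 = float(np.arctan2(link2_local[1], link2_local[0]))
    d = np.asarray(target, float) - np.asarray(root, float)
    r = np.hypot(d[..., 0], d[..., 1])
    if np.any(r > l1 + l2) or np.any(r < abs(l1 - l2)):
        raise ValueError(
            "attachment closure unreachable: pelvis pin outside the two-link workspace"
        )
    cos_g = np.clip((l1**2 + r**2 - l2**2) / (2.0 * l1 * r), -1.0, 1.0)
    gamma = np.arccos(cos_g)
    phi = np.arctan2(d[..., 1], d[..., 0])
    psi = phi + branch * gamma
    theta1 = psi - a1
    pivot = np.asarray(root, float) + l1 * np.stack(
        [np.cos(psi), np.sin(psi)], axis=-1
    )
    e = np.asarray(target, float) - pivot
    theta2 = np.arctan2(e[..., 1], e[..., 0]) - a2
    return theta1, theta2


class ReducedMap:
    """zeta -> q map for one assembled :class:`LiftingModel`."""

    def __init__(self, lm: "LiftingModel", exo_branch: float = -1.0):
        self.lm = lm
        self.nq = lm.nq
        L = lm.lengths
        self.l_sh, self.l_th, self.l_pe = L["shank"], L["thigh"], L["pelvis"]
        self.l_v, self.l_to = L["vertebra"], L["torso"]
        self.l_ua, self.l_fa = L["upper_arm"], L["forearm"]
        self.ankle = lm.ankle_world
        self.c = lm.lumbar.coefficients
        self.rest = lm.lumbar_rest
        self.sacral = lm.sacral_slope
        self.grip_local = lm.grip_local
        self.box_rest = lm.box.rest_pose
        self.handle_local = lm.box.handle_local
        # at grasp the box is upright and the hand frame sits at the
        # configured grasp angle; the weld keeps that relative transform
        self.box_rel_angle = -lm.hand_grasp_angle
        self.exo_branch = exo_branch

    # -- pieces ------------------------------------------------------

    def leg_angles(self, zeta: np.ndarray):
        a, k, hp = zeta[..., 0], zeta[..., 1], zeta[..., 2]
        th_sh = -a
        th_th = th_sh - k
        th_pe = th_th - hp
        return th_sh, th_th, th_pe

    def pelvis_pose(self, zeta: np.ndarray):
        th_sh, th_th, th_pe = self.leg_angles(zeta)
        r_sh = self.ankle - apply_rot(th_sh, np.array([0.0, -self.l_sh]))
        r_th = r_sh - apply_rot(th_th, np.array([0.0, -self.l_th]))
        return r_th, th_pe, th_th, th_sh

    def torso_pose(self, zeta: np.ndarray):
        r_pe, th_pe, _, _ = self.pelvis_pose(zeta)
        thL = zeta[..., 3]
        q_lum = self.rest - np.multiply.outer(thL, self.c)
        p = r_pe + apply_rot(th_pe, np.array([0.0, self.l_pe]))
        th = th_pe + self.sacral
        for i in range(5):
            th = th + q_lum[..., i]
            if i < 4:
                p = p + apply_rot(th, np.array([0.0, self.l_v]))
        return p, th  # torso origin (at the L1/L2 joint) and angle

    def hand_pose(self, zeta: np.ndarray) -> np.ndarray:
        """Grip-point pose (x, z, theta) of the hand frame."""
        p_to, th_to = self.torso_pose(zeta)
        th_ua = th_to + zeta[..., 4]
        th_fa = th_ua + zeta[..., 5]
        p_ua = p_to + apply_rot(th_to, np.array([0.0, self.l_to]))
        p_fa = p_ua + apply_rot(th_ua, np.array([0.0, -self.l_ua]))
        grip = p_fa + apply_rot(th_fa, self.grip_local)
        return np.concatenate([grip, th_fa[..., None]], axis=-1)

    # -- full map ----------------------------------------------------

    def q(self, zeta: np.ndarray, phase: int) -> np.ndarray:
        """Full generalized coordinates for a batch of zeta, given the phase."""
        zeta = np.asarray(zeta, dtype=float)
        batch = zeta.shape[:-1]
        q = np.zeros(batch + (self.nq,))
        r_pe, th_pe, th_th, th_sh = self.pelvis_pose(zeta)
        q[..., 3:5] = r_pe
        q[..., 5] = th_pe
        q[..., 6] = zeta[..., 2]  # hip
        q[..., 7] = zeta[..., 1]  # knee
        q[..., 8] = zeta[..., 0]  # ankle
        q[..., 9:14] = self.rest - np.multiply.outer(zeta[..., 3], self.c)
        q[..., 14] = zeta[..., 4]
        q[..., 15] = zeta[..., 5]
        if phase in (1, 2):
            q[..., 0:3] = self.box_rest
        else:
            hp = self.hand_pose(zeta)
            th_box = hp[..., 2] + self.box_rel_angle
            q[..., 2] = th_box
            q[..., 0:2] = hp[..., :2] - apply_rot(th_box, self.handle_local)
        if self.lm.with_exo:
            self._exo_q(zeta, q, r_pe, th_pe, th_th)
        return q

    def _exo_q(self, zeta, q, r_pe, th_pe, th_th):
        exo = self.lm.exo
        r_th = r_pe  # thigh frame origin coincides with the pelvis origin (hip)
        r_tm = r_th + apply_rot(th_th, exo.thigh_weld_offset)
        q[..., 16:18] = r_tm
        q[..., 18] = th_th
        hip_w = r_tm + apply_rot(th_th, exo.exo_hip_local)
        pin_w = r_pe + apply_rot(th_pe, exo.pelvis_pin_human)
        th_pm, th_if = two_link_closure(
            hip_w,
            pin_w,
            exo.pelvis_pivot_local,
            exo.interface_pin_local,
            branch=self.exo_branch,
        )
        q[..., 19] = th_pm - th_th
        q[..., 20] = th_if - th_pm
        p_to, th_to = self.torso_pose(zeta)
        r_trm = p_to + apply_rot(th_to, exo.trunk_weld_offset)
        q[..., 21:23] = r_trm
        q[..., 23] = th_to

    # -- inverse -----------------------------------------------------

    def zeta_from_q(self, q: np.ndarray) -> np.ndarray:
        """Extract the independent coordinates from a full q vector."""
        q = np.asarray(q, dtype=float)
        thL = -(q[..., 9:14] - self.rest).sum(axis=-1)
        return np.stack(
            [q[..., 8], q[..., 7], q[..., 6], thL, q[..., 14], q[..., 15]], axis=-1
        )


def standing_zeta(scenario_standing: dict | None = None) -> np.ndarray:
    z = np.zeros(N_ZETA)
    if scenario_standing:
        for i, name in enumerate(("ankle", "knee", "hip")):
            z[i] = scenario_standing.get(name, 0.0)
        z[4] = scenario_standing.get("shoulder", 0.0)
        z[5] = scenario_standing.get("elbow", 0.0)
    return z
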