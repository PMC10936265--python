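"""Assembly of the lifting system: human + box [+ exoskeleton].

Coordinate layout (q):
  0:3    box free body (x, z, theta)
  3:6    pelvis free base (x, z, theta)
  6,7,8  hip, knee, ankle revolutes
  9:14   five lumbar revolutes (L5/S1 up to L1/L2)
  14,15  shoulder, elbow revolutes
  16:24  exoskeleton (thigh module base 3, exo hip, interface pin,
         trunk module base 3), only when the device is worn

Angles are counter-clockwise in the sagittal plane with x forward, so
trunk flexion is negative and the lumbar coordinates are
extension-positive; the sacral slope is modeled as a fixed offset on L5
so the configured lordosis biases stack the torso vertically at rest.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .anthropometry import BoxSpec, HumanModelSpec
from .dynamics import (
    ConstraintSet,
    SingularConstraintError,
    WeldConstraint,
    forward_dynamics,
)
from .exoskeleton import (
    ExoSpec,
    attach_exoskeleton,
    beam_generalized_force,
)
from .lumbar import LumbarCoupling, coupling_rows
from .multibody import FIXED, FREE, REVOLUTE, Body, MultibodyModel, apply_rot

BOX_SLICE = slice(0, 3)
HUMAN_SLICE = slice(3, 16)
EXO_SLICE = slice(16, 24)
LUMBAR_COORDS = np.arange(9, 14)
#: actuated non-lumbar human joints, in reporting order
JOINT_COORDS = {"hip": 6, "knee": 7, "ankle": 8, "shoulder": 14, "elbow": 15}

PHASES = (1, 2, 3)


@dataclass
class IDResult:
    """Inverse-dynamics output at one (batch of) sample(s)."""

    tau: np.ndarray  # (..., nq) generalized applied torques (zeros off joints)
    lumbar_tau: np.ndarray  # (..., 5) per-joint lumbar torques, extension-positive
    lam: dict[str, np.ndarray]  # constraint forces per named constraint
    l5s1_moment: np.ndarray  # (...,) extension-positive intersegmental moment
    hand_wrench: np.ndarray | None = None
    u: np.ndarray | None = None


class LiftingModel:
    """Human + box (+ exoskeleton) multibody system with named frames."""

    def __init__(
        self,
        human: HumanModelSpec,
        box: BoxSpec,
        lumbar: LumbarCoupling,
        exo: ExoSpec | None = None,
        gravity: float = 9.81,
        hand_grasp_angle: float = 0.0,
    ):
        self.human = human
        self.box = box
        self.lumbar = lumbar
        self.exo = exo
        self.with_exo = exo is not None
        self.hand_grasp_angle = float(hand_grasp_angle)

        seg = human.segments
        bias_rad = np.deg2rad(lumbar.bias_extension_deg)
        self.lumbar_rest = bias_rad.copy()  # model coords are extension-positive
        sacral_slope = -bias_rad.sum()

        def B(name, jt, parent, anchor, segname=None, offset=0.0):
            s = seg[segname or name]
            return Body(
                name=name,
                joint_type=jt,
                parent=parent,
                anchor=np.asarray(anchor, float),
                mass=s.mass,
                com=s.com_offset,
                inertia=s.inertia_zz,
                angle_offset=offset,
            )

        l_pe = seg["pelvis"].length
        l_th = seg["thigh"].length
        l_sh = seg["shank"].length
        l_v = seg["l5"].length
        l_to = seg["torso"].length
        l_ua = seg["upper_arm"].length
        l_fa = seg["forearm_hand"].length

        bodies = [
            Body("box", FREE, -1, np.zeros(2), box.mass, np.zeros(2), box.inertia),
            B("pelvis", FREE, -1, (0.0, 0.0)),
            B("thigh", REVOLUTE, 1, (0.0, 0.0)),
            B("shank", REVOLUTE, 2, (0.0, -l_th)),
            B("foot", REVOLUTE, 3, (0.0, -l_sh)),
            B("l5", REVOLUTE, 1, (0.0, l_pe), offset=sacral_slope),
            B("l4", REVOLUTE, 5, (0.0, l_v)),
            B("l3", REVOLUTE, 6, (0.0, l_v)),
            B("l2", REVOLUTE, 7, (0.0, l_v)),
            B("torso", REVOLUTE, 8, (0.0, l_v)),
            B("upper_arm", REVOLUTE, 9, (0.0, l_to)),
            B("forearm_hand", REVOLUTE, 10, (0.0, -l_ua)),
        ]
        if exo is not None:
            es = exo.segments

            def E(name, jt, parent, anchor, offset=0.0):
                s = es[name]
                return Body(
                    name=name,
                    joint_type=jt,
                    parent=parent,
                    anchor=np.asarray(anchor, float),
                    mass=s.mass,
                    com=s.com_offset,
                    inertia=s.inertia_zz,
                    angle_offset=offset,
                )

            # orient the beam axis vertical in the neutral standing pose:
            # the pelvis-module angle there follows from the attachment
            # closure, which depends only on the (pose-invariant) offsets
            from .reduced import two_link_closure

            hip_rel = exo.thigh_weld_offset + exo.exo_hip_local
            th_pm0, _ = two_link_closure(
                hip_rel, exo.pelvis_pin_human, exo.pelvis_pivot_local,
                exo.interface_pin_local,
            )
            bodies += [
                E("thigh_module", FREE, -1, np.zeros(2)),
                E("pelvis_module", REVOLUTE, 12, exo.exo_hip_local),
                E("pelvis_interface", REVOLUTE, 13, exo.pelvis_pivot_local),
                E("trunk_module", FREE, -1, np.zeros(2)),
                E("beam_mount", FIXED, 13, exo.beam_mount_local, offset=-float(th_pm0)),
                E("roller_mount", FIXED, 15, exo.roller_local),
            ]

        self.model = MultibodyModel(bodies, gravity=gravity)
        self.nq = self.model.nq
        expected = 16 + (8 if self.with_exo else 0)
        if self.nq != expected:
            raise AssertionError(f"assembled {self.nq} coordinates, expected {expected}")

        self.grip_local = np.array([0.0, -l_fa])
        self.ankle_world = np.array([0.0, human.ankle_height])
        self.lengths = dict(
            pelvis=l_pe, thigh=l_th, shank=l_sh, vertebra=l_v,
            torso=l_to, upper_arm=l_ua, forearm=l_fa,
        )
        self.sacral_slope = sacral_slope
        self._subtree = [
            self.model.body_index(n)
            for n in ("l5", "l4", "l3", "l2", "torso", "upper_arm", "forearm_hand")
        ]
        self._phase_cache: dict[int, ConstraintSet] = {}

    # -- specs / bookkeeping ----------------------------------------

    @property
    def total_mass(self) -> float:
        return self.model.total_mass

    def body(self, name: str) -> int:
        return self.model.body_index(name)

    def human_dof(self) -> int:
        return HUMAN_SLICE.stop - HUMAN_SLICE.start

    # -- constraints -------------------------------------------------

    def phase_constraints(self, phase: int) -> ConstraintSet:
        """Active constraint rows for a lift phase.

        Feet-ground welds and the lumbar coupling are active throughout;
        the box is welded to the ground until lifted (phases 1-2); the
        hands are welded to the box from contact onward (phases 2-3); the
        eight exoskeleton attachment rows are active in every phase when
        the device is worn.
        """
        if phase not in PHASES:
            raise ValueError(f"phase must be one of {PHASES}")
        if phase in self._phase_cache:
            return self._phase_cache[phase]
        items = [
            WeldConstraint(
                "feet",
                body_a=self.body("foot"),
                local_a=np.zeros(2),
                target=self.ankle_world,
                target_angle=0.0,
            )
        ]
        if phase in (1, 2):
            items.append(
                WeldConstraint(
                    "box_ground",
                    body_a=self.body("box"),
                    local_a=np.zeros(2),
                    target=self.box.rest_pose[:2],
                    target_angle=self.box.rest_pose[2],
                )
            )
        if phase in (2, 3):
            items.append(
                WeldConstraint(
                    "hands_box",
                    body_a=self.body("box"),
                    local_a=self.box.handle_local,
                    body_b=self.body("forearm_hand"),
                    local_b=self.grip_local,
                    rel_angle=-self.hand_grasp_angle,
                )
            )
        items.extend(
            coupling_rows(LUMBAR_COORDS, self.lumbar_rest, self.lumbar, self.nq)
        )
        if self.with_exo:
            items.extend(attach_exoskeleton(self.model, self.exo))
        cs = ConstraintSet(self.model, items)
        self._phase_cache[phase] = cs
        return cs

    # -- applied generalized forces ----------------------------------

    def applied_force(
        self, q: np.ndarray, tau: np.ndarray, u: np.ndarray | None = None, kin=None
    ) -> np.ndarray:
        """Joint torques plus exoskeleton actuator and beam forces."""
        Q = np.array(tau, dtype=float, copy=True)
        if self.with_exo:
            if kin is None:
                kin = self.model.kinematics(q)
            Q = Q + beam_generalized_force(self.model, q, self.exo, kin)
            if u is not None:
                hip = self.model.coord_index("pelvis_module")
                Q[..., hip] += self.exo.actuator_max_torque * np.asarray(u, float)
        return Q

    # -- inverse dynamics --------------------------------------------

    def _lumbar_direction(self) -> np.ndarray:
        c, m2 = self.lumbar.coefficients, self.lumbar.m_max**2
        return c * m2 / np.sum(c**2 * m2)

    def inverse_dynamics(
        self,
        q: np.ndarray,
        qd: np.ndarray,
        qdd: np.ndarray,
        phase: int,
        hand_wrench: np.ndarray | None = None,
        u: np.ndarray | None = None,
    ) -> IDResult:
        """Joint torques and constraint forces realizing a motion.

        In phase 2 the hand-box wrench is statically indeterminate (the
        box rests on the ground while the hands load it) and must be
        supplied as a control; in phases 1/3 it is ``None``.  The five
        coupled lumbar torques share a one-parameter redundancy which is
        resolved by the minimum-normalized-torque split.
        """
        q = np.asarray(q, dtype=float)
        qd = np.asarray(qd, dtype=float)
        qdd = np.asarray(qdd, dtype=float)
        batch = q.shape[:-1]
        nq = self.nq
        cs = self.phase_constraints(phase)
        kin = self.model.kinematics(q)
        M = self.model.mass_matrix(q, kin)
        h = self.model.bias_forces(q, qd, kin)
        rhs = np.einsum("...ij,...j->...i", M, qdd) + h

        if self.with_exo:
            rhs = rhs - beam_generalized_force(self.model, q, self.exo, kin)
            if u is not None:
                hip = self.model.coord_index("pelvis_module")
                rhs[..., hip] -= self.exo.actuator_max_torque * np.asarray(u, float)

        G = cs.jacobian(q, kin)
        lam_names = [n for n in cs.names()]
        if phase == 2:
            if hand_wrench is None:
                raise ValueError("phase 2 requires the hand-box wrench as a control")
            w = np.asarray(hand_wrench, dtype=float)
            Gh = G[..., cs.rows_of("hands_box"), :]
            rhs = rhs - np.einsum("...ij,...i->...j", Gh, w)
            lam_names.remove("hands_box")
        lam_rows = [cs.rows_of(n) for n in lam_names]
        n_lam = sum(sl.stop - sl.start for sl in lam_rows)

        d_lum = self._lumbar_direction()
        joint_cols = list(JOINT_COORDS.values())
        n_tau = len(joint_cols) + 1
        if n_tau + n_lam != nq:
            raise AssertionError(
                f"inverse dynamics system not square: {n_tau}+{n_lam} != {nq}"
            )
        A = np.zeros(batch + (nq, nq))
        for k, c in enumerate(joint_cols):
            A[..., c, k] = 1.0
        A[..., LUMBAR_COORDS, len(joint_cols)] = d_lum
        col = n_tau
        for sl in lam_rows:
            m = sl.stop - sl.start
            A[..., :, col : col + m] = np.swapaxes(G[..., sl, :], -1, -2)
            col += m
        try:
            x = np.linalg.solve(A, rhs[..., None])[..., 0]
        except np.linalg.LinAlgError:
            raise SingularConstraintError(cs.row_labels) from None

        tau = np.zeros(batch + (nq,))
        for k, c in enumerate(joint_cols):
            tau[..., c] = x[..., k]
        s = x[..., len(joint_cols)]
        lumbar_tau = s[..., None] * d_lum
        tau[..., LUMBAR_COORDS] = lumbar_tau
        lam: dict[str, np.ndarray] = {}
        col = n_tau
        for name, sl in zip(lam_names, lam_rows):
            m = sl.stop - sl.start
            lam[name] = x[..., col : col + m]
            col += m
        if phase == 2:
            lam["hands_box"] = np.broadcast_to(w, batch + (3,)).copy()

        l5s1 = self._l5s1_moment(q, qd, qdd, kin, phase, lam)
        return IDResult(
            tau=tau,
            lumbar_tau=lumbar_tau,
            lam=lam,
            l5s1_moment=l5s1,
            hand_wrench=lam.get("hands_box"),
            u=None if u is None else np.asarray(u, float),
        )

    # -- L5/S1 intersegmental moment ---------------------------------

    def _l5s1_moment(
        self,
        q: np.ndarray,
        qd: np.ndarray,
        qdd: np.ndarray,
        kin,
        phase: int,
        lam: dict[str, np.ndarray],
        rates=None,
    ) -> np.ndarray:
        """Net sagittal moment transmitted across L5/S1, extension-positive.

        Newton-Euler balance of every body above the joint (vertebrae,
        torso, arms, plus the box once airborne), with the hand-box
        wrench (phase 2) and the exoskeleton trunk-attachment wrench as
        external actions.  This is the standard analysis-side low-back
        moment and is independent of how the coupled lumbar torques are
        split.
        """
        model = self.model
        if rates is None:
            rates = model.rates(q, qd, kin)
        P, _ = model.point_kinematics(
            kin, self.body("pelvis"), np.array([0.0, self.lengths["pelvis"]])
        )
        g_vec = np.array([0.0, -model.gravity])

        def cross(a, b):
            return a[..., 0] * b[..., 1] - a[..., 1] * b[..., 0]

        bodies = list(self._subtree)
        if phase == 3:
            bodies.append(self.body("box"))
        Mj = np.zeros(q.shape[:-1])
        for i in bodies:
            b = model.bodies[i]
            f, r = kin[i], rates[i]
            rc = apply_rot(f.theta, b.com)
            jcom = f.jpos + np.stack([-rc[..., 1], rc[..., 0]], axis=-1)[
                ..., :, None
            ] * f.jtheta[..., None, :]
            a_com = (
                r.acc0
                + r.alpha0[..., None] * np.stack([-rc[..., 1], rc[..., 0]], axis=-1)
                - (r.omega**2)[..., None] * rc
                + np.einsum("...ij,...j->...i", jcom, qdd)
            )
            alpha = r.alpha0 + np.einsum("...j,...j->...", f.jtheta, qdd)
            r_com = f.pos + rc
            Mj += b.inertia * alpha + cross(r_com - P, b.mass * (a_com - g_vec))
        if phase == 2 and "hands_box" in lam:
            w = lam["hands_box"]
            grip, _ = model.point_kinematics(
                kin, self.body("forearm_hand"), self.grip_local
            )
            # reaction of the box on the hands
            Mj -= cross(grip - P, -w[..., :2]) + (-w[..., 2])
        if self.with_exo and "exo_trunk" in lam:
            lt = lam["exo_trunk"]
            att, _ = model.point_kinematics(
                kin, self.body("torso"), self.exo.trunk_weld_offset
            )
            # the weld applies -lam to the torso side
            Mj -= cross(att - P, -lt[..., :2]) + (-lt[..., 2])
        return Mj

    # -- forward dynamics wrapper ------------------------------------

    def forward_dynamics(
        self,
        q: np.ndarray,
        qd: np.ndarray,
        tau: np.ndarray,
        phase: int,
        u: np.ndarray | None = None,
        baumgarte: tuple[float, float] = (10.0, 25.0),
    ):
        Q = self.applied_force(q, tau, u)
        return forward_dynamics(
            self.model, q, qd, Q, self.phase_constraints(phase), baumgarte
        )


def build_system(
    human: HumanModelSpec,
    box: BoxSpec,
    exo: ExoSpec | None = None,
    lumbar: LumbarCoupling | None = None,
    gravity: float = 9.81,
    hand_grasp_angle: float = 0.0,
) -> LiftingModel:
    """Assemble the human+box (16-coordinate) or +exoskeleton (24) system."""
    if lumbar is None:
        lumbar = LumbarCoupling(
            coefficients=[0.21, 0.25, 0.22, 0.18, 0.14],
            bias_extension_deg=[15.0, 12.0, 9.0, 6.0, 3.0],
        )
    return LiftingModel(
        human, box, lumbar, exo=exo, gravity=gravity, hand_grasp_angle=hand_grasp_angle
    )


def build_from_config(cfg: dict, with_exo: bool = False) -> LiftingModel:
    from .anthropometry import box_spec_from_config, human_spec_from_config
    from .exoskeleton import exo_spec_from_config

    human = human_spec_from_config(cfg)
    box = box_spec_from_config(cfg)
    exo = exo_spec_from_config(cfg) if with_exo else None
    lumbar = LumbarCoupling.from_config(cfg)
    return LiftingModel(
        human,
        box,
        lumbar,
        exo=exo,
        gravity=cfg.get("gravity", 9.81),
        hand_grasp_angle=cfg.get("scenario", {}).get("hand_grasp_angle", 0.0),
    )
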