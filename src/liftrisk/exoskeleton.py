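"""Passive+active back-support exoskeleton model.

The device has six segments and eight free coordinates: a thigh module
(3-DOF planar base, welded to the human thigh), an actuated hip revolute
to the pelvis module, a misalignment-compensation revolute to a small
pelvis interface (pinned to the human pelvis), a trunk module (3-DOF
base, welded to the torso), and two massless-joint mounts fixed on the
pelvis and trunk modules for the carbon-fiber beams.  Attached to the
human the eight attachment rows leave the device zero free DOF.

The carbon-fiber beam pack is modeled as a massless force element: at
every instant a cubic spline delta(s), s in [0, 1], is fitted to the
boundary conditions of the rigid pelvis mount (delta(0) = delta'(0) = 0)
and of the rollers on the trunk module (delta(1) = deltaL, delta''(1) = 0,
rollers transmit no moment), and small-deflection Euler-Bernoulli theory
converts the spline into end loads: tip shear 3 EI deltaL / L^3 and mount
moment 3 EI deltaL / L^2.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .anthropometry import SegmentParams
from .dynamics import Constraint, PointConstraint, WeldConstraint
from .multibody import MultibodyModel, apply_rot

log = logging.getLogger(__name__)

EXO_SEGMENTS = [
    "thigh_module",
    "pelvis_module",
    "pelvis_interface",
    "trunk_module",
    "beam_mount",
    "roller_mount",
]

#: deltaL/L beyond which small-deflection theory is flagged
DEFLECTION_VALIDITY = 0.3

N_ATTACHMENT_ROWS = 8


@dataclass
class BeamSpec:
    """Carbon-fiber beam pack: n_rods parallel rods of diameter d."""

    youngs_modulus: float = 166.0e9  # Pa
    diameter: float = 4.7e-3  # m
    n_rods: int = 3
    EI: float | None = None  # N m^2; derived when omitted

    def __post_init__(self) -> None:
        derived = (
            self.n_rods * self.youngs_modulus * np.pi * self.diameter**4 / 64.0
        )
        if self.EI is None:
            self.EI = derived
        elif abs(self.EI - derived) > 1e-6 * derived:
            raise ValueError(
                f"stored EI {self.EI} inconsistent with n E pi d^4/64 = {derived}"
            )
        if self.EI <= 0:
            raise ValueError("beam EI must be positive")


@dataclass
class BeamState:
    """Instantaneous beam geometry, spline and end loads.

    Loads are expressed in the beam frame (x transverse, z along the
    undeformed axis): forces the beam applies to the pelvis mount and to
    the rollers on the torso module.  The rollers cannot transmit a
    moment, so M_torso is identically zero.
    """

    L: float | np.ndarray
    deltaL: float | np.ndarray
    coeffs: np.ndarray  # (..., 4): delta(s) = a0 + a1 s + a2 s^2 + a3 s^3
    F_pelvis: np.ndarray | None = None  # (..., 2)
    M_pelvis: np.ndarray | float | None = None
    F_torso: np.ndarray | None = None
    M_torso: np.ndarray | float | None = None

    def deflection(self, s: np.ndarray) -> np.ndarray:
        s = np.asarray(s, dtype=float)
        a = self.coeffs
        return (
            a[..., 0, None]
            + a[..., 1, None] * s
            + a[..., 2, None] * s**2
            + a[..., 3, None] * s**3
        )


# boundary-condition matrix: delta(0), delta'(0), delta(1), delta''(1)
_BC = np.array(
    [
        [1.0, 0.0, 0.0, 0.0],
        [0.0, 1.0, 0.0, 0.0],
        [1.0, 1.0, 1.0, 1.0],
        [0.0, 0.0, 2.0, 6.0],
    ]
)
_BC_INV = np.linalg.inv(_BC)


def fit_beam_spline(L: float | np.ndarray, deltaL: float | np.ndarray) -> BeamState:
    """Cubic spline through the mount/roller boundary conditions.

    The four conditions (rigid mount: zero deflection and slope; rollers:
    deflection deltaL, zero curvature) determine the cubic uniquely.
    """
    L = np.asarray(L, dtype=float)
    deltaL = np.asarray(deltaL, dtype=float)
    if np.any(L <= 0):
        raise ValueError("beam mount/roller separation L must be > 0 (modules overlap)")
    rhs = np.zeros(np.broadcast(L, deltaL).shape + (4,))
    rhs[..., 2] = deltaL
    coeffs = rhs @ _BC_INV.T
    if np.any(np.abs(deltaL) > DEFLECTION_VALIDITY * L):
        log.warning(
            "beam deflection beyond small-deflection validity (|deltaL|/L > %.1f)",
            DEFLECTION_VALIDITY,
        )
    return BeamState(L=L, deltaL=deltaL, coeffs=coeffs)


def beam_end_loads(state: BeamState, spec: BeamSpec) -> BeamState:
    """Euler-Bernoulli end loads from the fitted spline.

    Moment is EI d2delta/dx2 and shear EI d3delta/dx3 with x = s L; the
    constant tip shear P = 3 EI deltaL / L^3 pushes the rollers back
    toward the undeformed axis, and the mount reacts with the opposite
    force plus the clamping moment P L.  The two end loads are an
    equilibrated force system on the massless beam.
    """
    a2 = state.coeffs[..., 2]
    a3 = state.coeffs[..., 3]
    L = np.asarray(state.L, dtype=float)
    P = -6.0 * a3 * spec.EI / L**3  # = 3 EI deltaL / L^3
    zeros = np.zeros_like(P)
    state.F_torso = np.stack([-P, zeros], axis=-1)
    state.F_pelvis = np.stack([P, zeros], axis=-1)
    # clamping reaction on the pelvis mount; equals -(EI delta''(0) / L^2)
    state.M_pelvis = -2.0 * a2 * spec.EI / L**2
    state.M_torso = zeros
    return state


def actuator_torque(u: np.ndarray, max_torque: float = 25.0) -> np.ndarray:
    """Hip actuator torque for a normalized control signal |u| <= 1."""
    return max_torque * np.asarray(u, dtype=float)


@dataclass
class ExoSpec:
    """Exoskeleton segments, attachment geometry, beam and actuator."""

    segments: dict[str, SegmentParams]
    thigh_weld_offset: np.ndarray
    exo_hip_local: np.ndarray
    pelvis_pivot_local: np.ndarray
    interface_pin_local: np.ndarray
    pelvis_pin_human: np.ndarray
    trunk_weld_offset: np.ndarray
    beam_mount_local: np.ndarray
    roller_local: np.ndarray
    beam: BeamSpec = field(default_factory=BeamSpec)
    actuator_max_torque: float = 25.0
    total_mass: float = 9.12

    N_SEGMENTS = 6
    N_DOF = 8

    def __post_init__(self) -> None:
        for name in (
            "thigh_weld_offset",
            "exo_hip_local",
            "pelvis_pivot_local",
            "interface_pin_local",
            "pelvis_pin_human",
            "trunk_weld_offset",
            "beam_mount_local",
            "roller_local",
        ):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        missing = [n for n in EXO_SEGMENTS if n not in self.segments]
        if missing:
            raise ValueError(f"exoskeleton spec missing segments: {missing}")
        mass = sum(s.mass for s in self.segments.values())
        if abs(mass - self.total_mass) > 1e-9 * max(self.total_mass, 1.0):
            raise ValueError(
                f"exoskeleton segment masses sum to {mass}, expected {self.total_mass}"
            )


def exo_spec_from_config(cfg: dict) -> ExoSpec:
    ec = cfg["exoskeleton"]
    masses = ec["segment_masses"]
    # nominal module extents; CoM near the module centre, inertia ~ m r^2
    geometry = {
        "thigh_module": (0.30, np.array([0.0, 0.15])),
        "pelvis_module": (0.20, np.array([-0.05, 0.05])),
        "pelvis_interface": (0.08, np.array([0.0, 0.04])),
        "trunk_module": (0.25, np.array([0.0, 0.0])),
        "beam_mount": (0.05, np.array([0.0, 0.0])),
        "roller_mount": (0.05, np.array([0.0, 0.0])),
    }
    segments = {}
    for name in EXO_SEGMENTS:
        length, com = geometry[name]
        m = float(masses[name])
        segments[name] = SegmentParams(
            name=name,
            mass=m,
            com_offset=com,
            inertia_zz=m * (0.35 * length) ** 2,
            length=length,
        )
    bc = ec["beam"]
    return ExoSpec(
        segments=segments,
        thigh_weld_offset=ec["thigh_weld_offset"],
        exo_hip_local=ec["exo_hip_local"],
        pelvis_pivot_local=ec["pelvis_pivot_local"],
        interface_pin_local=ec["interface_pin_local"],
        pelvis_pin_human=ec["pelvis_pin_human"],
        trunk_weld_offset=ec["trunk_weld_offset"],
        beam_mount_local=ec["beam_mount_local"],
        roller_local=ec["roller_local"],
        beam=BeamSpec(
            youngs_modulus=float(bc["youngs_modulus"]),
            diameter=float(bc["diameter"]),
            n_rods=int(bc["n_rods"]),
        ),
        actuator_max_torque=float(ec["actuator_max_torque"]),
        total_mass=float(ec["total_mass"]),
    )


def attach_exoskeleton(model: MultibodyModel, spec: ExoSpec) -> list[Constraint]:
    """The eight attachment rows: thigh weld, pelvis pin, trunk weld."""
    try:
        thigh = model.body_index("thigh")
        pelvis = model.body_index("pelvis")
        torso = model.body_index("torso")
        thigh_module = model.body_index("thigh_module")
        interface = model.body_index("pelvis_interface")
        trunk_module = model.body_index("trunk_module")
    except KeyError as exc:
        raise ValueError(f"cannot attach exoskeleton: {exc}") from None
    items: list[Constraint] = [
        WeldConstraint(
            "exo_thigh",
            body_a=thigh_module,
            local_a=np.zeros(2),
            body_b=thigh,
            local_b=spec.thigh_weld_offset,
        ),
        PointConstraint(
            "exo_pelvis",
            body_a=interface,
            local_a=spec.interface_pin_local,
            body_b=pelvis,
            local_b=spec.pelvis_pin_human,
        ),
        WeldConstraint(
            "exo_trunk",
            body_a=trunk_module,
            local_a=np.zeros(2),
            body_b=torso,
            local_b=spec.trunk_weld_offset,
        ),
    ]
    n = sum(it.rows for it in items)
    if n != N_ATTACHMENT_ROWS:
        raise AssertionError(f"attachment rows total {n}, expected {N_ATTACHMENT_ROWS}")
    return items


def beam_state_from_kinematics(
    model: MultibodyModel, kin, spec: ExoSpec
) -> BeamState:
    """Beam geometry from the current pose: roller position in the beam frame.

    The beam frame sits at the beam-mount origin with its axis along the
    mount's +z direction; L is the axial and deltaL the transverse roller
    coordinate.
    """
    mount = model.body_index("beam_mount")
    roller = model.body_index("roller_mount")
    p_m, _ = model.point_kinematics(kin, mount, np.zeros(2))
    p_r, _ = model.point_kinematics(kin, roller, np.zeros(2))
    th = kin[mount].theta
    rel = apply_rot(-th, p_r - p_m)
    state = fit_beam_spline(rel[..., 1], rel[..., 0])
    return beam_end_loads(state, spec.beam)


def beam_generalized_force(
    model: MultibodyModel, q: np.ndarray, spec: ExoSpec, kin=None
) -> np.ndarray:
    """Generalized force of the beam end loads on the assembled system."""
    q = np.asarray(q, dtype=float)
    if kin is None:
        kin = model.kinematics(q)
    state = beam_state_from_kinematics(model, kin, spec)
    mount = model.body_index("beam_mount")
    roller = model.body_index("roller_mount")
    th = kin[mount].theta
    _, j_m = model.point_kinematics(kin, mount, np.zeros(2))
    _, j_r = model.point_kinematics(kin, roller, np.zeros(2))
    F_p = apply_rot(th, state.F_pelvis)
    F_t = apply_rot(th, state.F_torso)
    Q = np.einsum("...kj,...k->...j", j_m, F_p)
    Q += np.einsum("...kj,...k->...j", j_r, F_t)
    Q += np.asarray(state.M_pelvis)[..., None] * kin[mount].jtheta
    return Q
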