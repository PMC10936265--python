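"""Anthropometric scaling of the planar human model.

The human is an 11-segment sagittal-plane model: foot, shank and thigh
(left/right merged), pelvis, four free lumbar vertebra bodies (L5-L2), a
torso segment that carries L1, the thorax, head and neck, and merged upper
arm and forearm+hand segments.  Segment masses, centre-of-mass locations
and moments of inertia are scaled from literature segment-inertia fraction
tables by the subject's stature and body mass.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

SEGMENT_ORDER = [
    "pelvis",
    "thigh",
    "shank",
    "foot",
    "l5",
    "l4",
    "l3",
    "l2",
    "torso",
    "upper_arm",
    "forearm_hand",
]

_REQUIRED_FIELDS = ("mass_frac", "length_frac", "com_frac", "rgyr_frac")


@dataclass
class SegmentParams:
    """Inertial and geometric parameters of one model segment."""

    name: str
    mass: float  # kg
    com_offset: np.ndarray  # m, CoM in the segment frame (origin = proximal joint)
    inertia_zz: float  # kg m^2 about the CoM
    length: float  # m

    def __post_init__(self) -> None:
        self.com_offset = np.asarray(self.com_offset, dtype=float)
        if self.mass < 0:
            raise ValueError(f"segment {self.name}: mass must be >= 0")
        if self.length <= 0:
            raise ValueError(f"segment {self.name}: length must be > 0")
        if self.inertia_zz < 0:
            raise ValueError(f"segment {self.name}: inertia must be >= 0")


@dataclass
class HumanModelSpec:
    """Scaled human model: 11 segments, 13 generalized coordinates."""

    height: float
    total_mass: float
    segments: dict[str, SegmentParams]
    ankle_height: float

    N_SEGMENTS = 11
    N_DOF = 13

    def __post_init__(self) -> None:
        missing = [n for n in SEGMENT_ORDER if n not in self.segments]
        if missing:
            raise ValueError(f"human model missing segments: {missing}")
        total = sum(s.mass for s in self.segments.values())
        if self.total_mass > 0 and abs(total - self.total_mass) > 1e-9 * self.total_mass:
            raise ValueError(
                f"segment masses sum to {total}, expected {self.total_mass}"
            )


@dataclass
class BoxSpec:
    """The lifted box: one free planar body (x, z, theta)."""

    mass: float
    width: float
    height: float
    x: float = 0.42  # rest position of the box centre, forward of the ankles
    handle_height_frac: float = 1.0

    N_DOF = 3

    def __post_init__(self) -> None:
        if self.mass <= 0:
            raise ValueError("box mass must be > 0")
        if self.width <= 0 or self.height <= 0:
            raise ValueError("box dimensions must be > 0")

    @property
    def inertia(self) -> float:
        return self.mass * (self.width**2 + self.height**2) / 12.0

    @property
    def rest_pose(self) -> np.ndarray:
        """(x, z, theta) with the box sitting on the ground."""
        return np.array([self.x, self.height / 2.0, 0.0])

    @property
    def handle_local(self) -> np.ndarray:
        """Handle point in the box frame (origin at the centre)."""
        return np.array([0.0, self.height * (self.handle_height_frac - 0.5)])


@dataclass
class GeneralizedState:
    """Time-stamped generalized positions and velocities."""

    q: np.ndarray
    qdot: np.ndarray
    time: float = 0.0

    def __post_init__(self) -> None:
        self.q = np.asarray(self.q, dtype=float)
        self.qdot = np.asarray(self.qdot, dtype=float)
        if self.q.shape != self.qdot.shape:
            raise ValueError("q and qdot must have the same shape")


def scale_anthropometry(
    height: float, total_mass: float, table: dict
) -> dict[str, SegmentParams]:
    """Scale a segment-fraction table to a subject's stature and mass.

    ``table`` maps segment name -> {mass_frac, length_frac, com_frac,
    rgyr_frac}.  Mass fractions are renormalized to sum to exactly one, so
    the returned segment masses sum to ``total_mass`` to machine precision.
    """
    if height <= 0:
        raise ValueError("height must be > 0")
    if total_mass < 0:
        raise ValueError("total_mass must be >= 0")
    for name in SEGMENT_ORDER:
        if name not in table:
            raise KeyError(f"anthropometric table has no entry for segment {name!r}")
        row = table[name]
        for f in _REQUIRED_FIELDS:
            if f not in row:
                raise KeyError(f"segment {name!r}: table entry missing {f!r}")
    frac_sum = sum(float(table[n]["mass_frac"]) for n in SEGMENT_ORDER)
    segments: dict[str, SegmentParams] = {}
    for name in SEGMENT_ORDER:
        row = table[name]
        mass = total_mass * float(row["mass_frac"]) / frac_sum
        length = height * float(row["length_frac"])
        # vertebrae/torso extend upward from their proximal joint, limb
        # segments hang downward; the foot is handled by the assembler.
        direction = 1.0 if name in ("pelvis", "l5", "l4", "l3", "l2", "torso") else -1.0
        com = np.array([0.0, direction * float(row["com_frac"]) * length])
        inertia = mass * (float(row["rgyr_frac"]) * length) ** 2
        segments[name] = SegmentParams(
            name=name, mass=mass, com_offset=com, inertia_zz=inertia, length=length
        )
    return segments


def human_spec_from_config(cfg: dict) -> HumanModelSpec:
    hc = cfg["human"]
    segments = scale_anthropometry(hc["height"], hc["total_mass"], hc["segments"])
    # foot CoM sits forward of the ankle and slightly below it
    foot = segments["foot"]
    ankle_h = hc["ankle_height_frac"] * hc["height"]
    foot.com_offset = np.array(
        [hc.get("foot_forward_frac", 0.19) * foot.length, -0.6 * ankle_h]
    )
    return HumanModelSpec(
        height=hc["height"],
        total_mass=hc["total_mass"],
        segments=segments,
        ankle_height=ankle_h,
    )


def box_spec_from_config(cfg: dict) -> BoxSpec:
    bc = cfg["box"]
    return BoxSpec(
        mass=bc["mass"],
        width=bc["width"],
        height=bc["height"],
        x=bc.get("x", 0.42),
        handle_height_frac=bc.get("handle_height_frac", 1.0),
    )
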