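"""Synthetic stoop-squat reference lifts and marker-based inverse kinematics.

No public recording of the original lifting experiment exists, so the
reference motion is generated: minimum-jerk interpolation in the reduced
coordinates between a standing keyframe, a grasp keyframe (solved so the
hands sit exactly on the box handle) and a final standing keyframe, over
three phases -- reach down, load transfer onto the hands (posture held,
hand force ramping to the box weight), and lift back up.  The result is
kinematically consistent with every phase's constraint set, starts and
ends at rest, and is therefore a feasible tracking target and initial
guess for the optimal control problems.

Virtual markers (two per major segment) are produced by forward
kinematics plus seeded Gaussian noise; :func:`inverse_kinematics` maps
marker trajectories back to generalized coordinates by per-frame
nonlinear least squares over the reduced coordinates, which enforces the
lumbar coupling and planted feet during the fit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares, root

from .assembly import LiftingModel
from .reduced import N_ZETA, ReducedMap, standing_zeta
from .trajectory import Trajectory

_STENCIL_H = 1.0e-3  # s, five-point time stencil for qd/qdd


@dataclass
class LiftScenario:
    """Keyframes, phase durations and marker-noise settings of one lift."""

    phase_durations: np.ndarray = field(
        default_factory=lambda: np.array([1.2, 0.4, 1.4])
    )
    peak_lumbar_flexion_deg: float = 55.0
    standing: np.ndarray = field(default_factory=lambda: np.zeros(N_ZETA))
    grasp_guess: np.ndarray = field(
        default_factory=lambda: np.array([0.35, -0.9, 1.2, 0.0, 1.4, 0.1])
    )
    marker_noise_std: float = 0.0
    seed: int = 42

    def __post_init__(self) -> None:
        self.phase_durations = np.asarray(self.phase_durations, dtype=float)
        self.standing = np.asarray(self.standing, dtype=float)
        self.grasp_guess = np.asarray(self.grasp_guess, dtype=float)
        if self.phase_durations.shape != (3,) or np.any(self.phase_durations <= 0):
            raise ValueError("need three positive phase durations")

    @classmethod
    def from_config(cls, cfg: dict) -> "LiftScenario":
        sc = cfg["scenario"]
        grasp = sc.get("grasp", {})
        guess = np.array(
            [
                grasp.get("ankle", 0.35),
                grasp.get("knee", -0.9),
                grasp.get("hip", 1.2),
                0.0,
                grasp.get("shoulder", 1.4),
                grasp.get("elbow", 0.1),
            ]
        )
        return cls(
            phase_durations=np.asarray(sc["phase_durations"], float),
            peak_lumbar_flexion_deg=float(sc["peak_lumbar_flexion_deg"]),
            standing=standing_zeta(sc.get("standing")),
            grasp_guess=guess,
            marker_noise_std=float(sc.get("marker_noise_std", 0.0)),
            seed=int(sc.get("seed", 42)),
        )


def min_jerk(tau: np.ndarray) -> np.ndarray:
    """C2 minimum-jerk profile: 0 -> 1 with zero end velocity/acceleration."""
    tau = np.clip(tau, 0.0, 1.0)
    return 10 * tau**3 - 15 * tau**4 + 6 * tau**5


def marker_set(lm: LiftingModel) -> list[tuple[str, np.ndarray]]:
    """Two virtual markers per major segment (sagittal gait-lab style)."""
    L = lm.lengths
    ah = lm.human.ankle_height
    out = []
    for name, direction, length in (
        ("foot", 1.0, 0.6 * lm.human.segments["foot"].length),
        ("shank", -1.0, L["shank"]),
        ("thigh", -1.0, L["thigh"]),
        ("pelvis", 1.0, L["pelvis"]),
        ("torso", 1.0, L["torso"]),
        ("upper_arm", -1.0, L["upper_arm"]),
        ("forearm_hand", -1.0, L["forearm"]),
    ):
        if name == "foot":
            out.append(("foot_prox", "foot", np.array([0.0, -0.5 * ah])))
            out.append(("foot_dist", "foot", np.array([length, -0.5 * ah])))
        else:
            out.append((f"{name}_prox", name, np.array([0.03, direction * 0.25 * length])))
            out.append((f"{name}_dist", name, np.array([0.03, direction * 0.80 * length])))
    return [(mname, lm.body(bname), local) for mname, bname, local in out]


def solve_grasp_pose(
    rmap: ReducedMap, scenario: LiftScenario, max_residual: float = 1e-9
) -> np.ndarray:
    """Grasp keyframe: hand frame exactly on the box handle.

    Ankle, knee and the peak lumbar flexion are taken from the scenario;
    hip, shoulder and elbow are solved from the three hand-pose
    conditions (handle position and configured grasp angle).
    """
    lm = rmap.lm
    handle_world = lm.box.rest_pose[:2] + lm.box.handle_local  # box upright
    target = np.array([handle_world[0], handle_world[1], lm.hand_grasp_angle])
    zeta = scenario.grasp_guess.copy()
    zeta[3] = np.deg2rad(scenario.peak_lumbar_flexion_deg)

    def fun(x):
        z = zeta.copy()
        z[[2, 4, 5]] = x
        return rmap.hand_pose(z) - target

    sol = root(fun, zeta[[2, 4, 5]], tol=1e-12)
    if not sol.success or np.abs(fun(sol.x)).max() > max_residual:
        raise RuntimeError(
            "grasp keyframe projection failed: hand cannot reach the box handle "
            f"(residual {np.abs(fun(sol.x)).max():.3g})"
        )
    zeta[[2, 4, 5]] = sol.x
    return zeta


class ReferenceMotion:
    """A generated lift: zeta(t), hand-force ramp, and sampling helpers."""

    def __init__(self, lm: LiftingModel, scenario: LiftScenario):
        self.lm = lm
        self.scenario = scenario
        self.rmap = ReducedMap(lm)
        self.zeta_stand = scenario.standing.copy()
        self.zeta_grasp = solve_grasp_pose(self.rmap, scenario)
        self.durations = scenario.phase_durations.copy()
        self.t_bounds = np.concatenate([[0.0], np.cumsum(self.durations)])
        self.total_time = float(self.t_bounds[-1])

    # -- profiles ----------------------------------------------------

    def phase_of(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        ph = np.ones(t.shape, dtype=int)
        ph[t > self.t_bounds[1]] = 2
        ph[t > self.t_bounds[2]] = 3
        return ph

    def zeta(self, t: np.ndarray) -> np.ndarray:
        """Piecewise minimum-jerk reduced-coordinate profile (C2 in time)."""
        t = np.asarray(t, dtype=float)
        T0, T1, T2, T3 = self.t_bounds
        s1 = min_jerk((t - T0) / (T1 - T0))[..., None]
        s3 = min_jerk((t - T2) / (T3 - T2))[..., None]
        down = self.zeta_stand + s1 * (self.zeta_grasp - self.zeta_stand)
        up = self.zeta_grasp + s3 * (self.zeta_stand - self.zeta_grasp)
        out = np.where((t <= T1)[..., None], down, np.broadcast_to(self.zeta_grasp, down.shape))
        out = np.where((t > T2)[..., None], up, out)
        return out

    def hand_wrench(self, t: np.ndarray) -> np.ndarray:
        """Load-transfer ramp: hand force on the box, 0 -> full weight."""
        t = np.asarray(t, dtype=float)
        T1, T2 = self.t_bounds[1], self.t_bounds[2]
        s = min_jerk((t - T1) / (T2 - T1))
        w = np.zeros(t.shape + (3,))
        w[..., 1] = s * self.lm.box.mass * self.lm.model.gravity
        return w

    def states(self, t: np.ndarray, phase: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """q, qd, qdd at times ``t`` using the given phase's coordinate map."""
        t = np.asarray(t, dtype=float)
        offs = np.array([-2.0, -1.0, 0.0, 1.0, 2.0]) * _STENCIL_H
        qs = np.stack(
            [self.rmap.q(self.zeta(t + o), phase) for o in offs], axis=0
        )
        q = qs[2]
        qd = (qs[0] - 8 * qs[1] + 8 * qs[3] - qs[4]) / (12 * _STENCIL_H)
        qdd = (-qs[0] + 16 * qs[1] - 30 * qs[2] + 16 * qs[3] - qs[4]) / (
            12 * _STENCIL_H**2
        )
        return q, qd, qdd

    # -- sampling ----------------------------------------------------

    def sample(self, hz: float = 100.0, with_exo_control: bool = False) -> Trajectory:
        """Uniformly sampled trajectory with torques and constraint forces."""
        n = max(int(round(self.total_time * hz)) + 1, 7)
        t = np.linspace(0.0, self.total_time, n)
        phases = self.phase_of(t)
        nq = self.lm.nq
        q = np.zeros((n, nq))
        qd = np.zeros((n, nq))
        qdd = np.zeros((n, nq))
        tau = np.zeros((n, nq))
        l5s1 = np.zeros(n)
        lam_store: dict[str, np.ndarray] = {}
        for phase in (1, 2, 3):
            mask = phases == phase
            if not mask.any():
                continue
            qp, qdp, qddp = self.states(t[mask], phase)
            q[mask], qd[mask], qdd[mask] = qp, qdp, qddp
            w = self.hand_wrench(t[mask]) if phase == 2 else None
            u = np.zeros(mask.sum()) if (self.lm.with_exo and with_exo_control) else (
                np.zeros(mask.sum()) if self.lm.with_exo else None
            )
            res = self.lm.inverse_dynamics(qp, qdp, qddp, phase, hand_wrench=w, u=u)
            tau[mask] = res.tau
            l5s1[mask] = res.l5s1_moment
            for name, arr in res.lam.items():
                if name not in lam_store:
                    lam_store[name] = np.zeros((n, arr.shape[-1]))
                lam_store[name][mask] = arr
        thL = self.rmap.zeta_from_q(q)[:, 3]
        extras = {
            "l5s1_moment": l5s1,
            "lumbar_flexion_deg": np.rad2deg(thL),
        }
        if self.lm.with_exo:
            extras["u"] = np.zeros(n)
            extras.update(_beam_extras(self.lm, q))
        return Trajectory(
            time=t, q=q, qd=qd, qdd=qdd, tau=tau, phase=phases, lam=lam_store,
            extras=extras,
        )

    def markers(self, hz: float = 100.0, rng: np.random.Generator | None = None) -> pd.DataFrame:
        """Virtual-marker trajectories with seeded Gaussian noise."""
        if rng is None:
            rng = np.random.default_rng(self.scenario.seed)
        n = max(int(round(self.total_time * hz)) + 1, 7)
        t = np.linspace(0.0, self.total_time, n)
        phases = self.phase_of(t)
        q = np.zeros((n, self.lm.nq))
        for phase in (1, 2, 3):
            mask = phases == phase
            if mask.any():
                q[mask] = self.rmap.q(self.zeta(t[mask]), phase)
        kin = self.lm.model.kinematics(q)
        cols: dict[str, np.ndarray] = {"time": t}
        for mname, body, local in marker_set(self.lm):
            pos, _ = self.lm.model.point_kinematics(kin, body, local)
            noise = rng.normal(0.0, self.scenario.marker_noise_std, pos.shape)
            cols[f"{mname}_x"] = pos[:, 0] + noise[:, 0]
            cols[f"{mname}_z"] = pos[:, 1] + noise[:, 1]
        return pd.DataFrame(cols)


def _beam_extras(lm: LiftingModel, q: np.ndarray) -> dict[str, np.ndarray]:
    """Beam geometry/load time series for exported exoskeleton trajectories."""
    from .exoskeleton import beam_state_from_kinematics

    kin = lm.model.kinematics(q)
    st = beam_state_from_kinematics(lm.model, kin, lm.exo)
    return {
        "beam_L_m": np.asarray(st.L),
        "beam_deltaL_m": np.asarray(st.deltaL),
        "beam_mount_moment_Nm": np.asarray(st.M_pelvis),
        "beam_roller_force_N": np.asarray(st.F_torso)[..., 0],
    }


def generate_reference(
    scenario: LiftScenario, lm: LiftingModel, hz: float = 100.0
) -> tuple[Trajectory, pd.DataFrame, ReferenceMotion]:
    """Generate the synthetic lift: trajectory, markers, and the motion object."""
    motion = ReferenceMotion(lm, scenario)
    return motion.sample(hz=hz), motion.markers(hz=hz), motion


@dataclass
class IKResult:
    zeta: np.ndarray  # (n, 6)
    q: np.ndarray  # (n, nq) human coordinates posed per frame (phase-1 map)
    residual_rms: np.ndarray  # (n,) marker residual RMS per frame, m
    failed_frames: list[int] = field(default_factory=list)


def inverse_kinematics(
    markers: pd.DataFrame,
    lm: LiftingModel,
    zeta0: np.ndarray | None = None,
) -> IKResult:
    """Per-frame least-squares fit of the model to marker positions.

    The fit runs over the six reduced coordinates, so the lumbar coupling
    and the planted feet are enforced exactly during the fit.  Frames
    whose solver does not converge are flagged and linearly interpolated.
    """
    rmap = ReducedMap(lm)
    names = [m for m, _, _ in marker_set(lm)]
    missing = [m for m in names if f"{m}_x" not in markers.columns]
    present = [m for m in names if f"{m}_x" in markers.columns]
    if 2 * len(present) < N_ZETA:
        raise ValueError(
            f"not enough marker coordinates to pose the model: {2 * len(present)} < {N_ZETA}"
            + (f" (missing {missing})" if missing else "")
        )
    mset = [(m, b, l) for (m, b, l) in marker_set(lm) if m in present]
    meas = np.stack(
        [markers[[f"{m}_x", f"{m}_z"]].to_numpy() for m, _, _ in mset], axis=1
    )  # (n, nm, 2)
    n = meas.shape[0]

    def residual(z, target):
        q = rmap.q(z, 1)
        kin = lm.model.kinematics(q)
        out = np.empty((len(mset), 2))
        for k, (_, body, local) in enumerate(mset):
            pos, _ = lm.model.point_kinematics(kin, body, local)
            out[k] = pos - target[k]
        return out.ravel()

    zeta = np.zeros((n, N_ZETA))
    rms = np.zeros(n)
    failed: list[int] = []
    z = np.zeros(N_ZETA) if zeta0 is None else np.asarray(zeta0, float).copy()
    for i in range(n):
        sol = least_squares(residual, z, args=(meas[i],), method="lm")
        if not sol.success:
            failed.append(i)
            zeta[i] = np.nan
            continue
        z = sol.x
        zeta[i] = z
        rms[i] = np.sqrt(np.mean(sol.fun**2))
    if failed:
        good = np.setdiff1d(np.arange(n), failed)
        for j in range(N_ZETA):
            zeta[failed, j] = np.interp(failed, good, zeta[good, j])
    q = rmap.q(zeta, 1)
    return IKResult(zeta=zeta, q=q, residual_rms=rms, failed_frames=failed)
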