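"""Three-phase trajectory optimization of the lifting task.

The optimal control problem (reach the box, transfer its load onto the
hands, lift and stand back up) is transcribed with an inverse-dynamics
collocation scheme: the decision variables are the knot values of the six
independent coordinates (cubic-spline interpolated with clamped, i.e.
rest-to-rest, ends), the free phase durations, the statically
indeterminate hand-force ramp of phase 2, and the exoskeleton motor
control.  Full states follow from the reduced kinematic map, so the
multibody dynamics and every kinematic constraint of the active phase are
satisfied exactly at the collocation nodes by construction; joint torques
and contact/attachment forces come from batched inverse dynamics, and
physical realizability is imposed as path inequalities (unilateral ground
contact, friction cones at feet and hands, open-grip moment bound, torque
limits, human-exoskeleton interaction-force limits, |u| <= 1).

The resulting dense NLP (~60-90 variables) is solved with SLSQP.  A
best-feasible-iterate safeguard returns the lowest-cost point among all
evaluated iterates that satisfy the constraints, so warm-starting a
predictive problem from a feasible tracking solution can never return
something worse than the start.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.optimize import minimize

from .assembly import JOINT_COORDS, LUMBAR_COORDS, HUMAN_SLICE, LiftingModel
from .dynamics import ConstraintSet
from .exoskeleton import beam_generalized_force
from .reduced import N_ZETA, ReducedMap
from .risk import (
    CostSpec,
    clbl_cost_integrand,
    hyb_cost_integrand,
    plbl_cost_integrand,
)
from .synthetic import ReferenceMotion
from .trajectory import Trajectory

_H = 1.0e-3  # s, central-difference step for spline-state derivatives
#: feasibility tolerance on the scaled (O(1)) constraint rows
FEAS_TOL = 1.0e-4
_F0 = 300.0  # N, force scale for contact-force inequality rows

#: generous joint-range bounds on the reduced coordinates (rad)
ZETA_BOUNDS = np.array(
    [
        [-1.0, 1.0],  # ankle
        [-2.6, 0.5],  # knee
        [-0.5, 2.6],  # hip
        [-0.25, 1.2],  # lumbar flexion (~69 deg, physiological range)
        [-1.0, 3.0],  # shoulder
        [-2.6, 2.6],  # elbow
    ]
)
W_SCALE = np.array([200.0, 200.0, 20.0])  # hand wrench scaling (N, N, N m)


@dataclass
class PhaseSpec:
    """One lift phase of the transcription."""

    index: int
    duration: float
    fixed_duration: bool
    n_intervals: int

    def __post_init__(self) -> None:
        if self.index not in (1, 2, 3):
            raise ValueError("phase index must be 1, 2 or 3")
        if self.duration <= 0:
            raise ValueError("phase duration must be positive")
        if self.n_intervals + 1 < 5:
            raise ValueError("each phase needs at least 5 shooting nodes")


@dataclass
class OCPSpec:
    """Model variant, objective and bounds of one optimal control problem."""

    variant: str  # 'HO' | 'HwE'
    cost: CostSpec
    phases: list[PhaseSpec]
    friction_mu: float = 0.8
    torque_limits: dict = field(
        default_factory=lambda: dict(hip=320.0, knee=320.0, ankle=250.0,
                                     shoulder=160.0, elbow=130.0)
    )
    interaction_force_limit: float = 200.0
    interaction_moment_limit: float = 60.0
    hand_moment_limit: float = 15.0
    duration_bounds: tuple[float, float] = (0.2, 3.0)
    smoothness_weight: float = 5.0e-5
    maxiter: int = 160
    ftol: float = 1.0e-6
    eps: float = 1.0e-6

    def __post_init__(self) -> None:
        if self.variant not in ("HO", "HwE"):
            raise ValueError("variant must be 'HO' or 'HwE'")
        if len(self.phases) != 3:
            raise ValueError("need exactly three phases")

    @classmethod
    def from_config(
        cls,
        cfg: dict,
        variant: str,
        kind: str,
        reference_durations: np.ndarray,
        fix_durations: bool | None = None,
    ) -> "OCPSpec":
        oc = cfg["ocp"]
        rc = cfg["risk"]
        if fix_durations is None:
            fix_durations = kind == "LSQ"  # tracking keeps the measured timing
        cost = CostSpec(
            kind=kind,
            tracking_weight=rc.get("lsq_tracking_weight", 1.0),
            exo_weight=rc.get("lsq_exo_weight", 5.0e-2),
            reg_weight=rc.get("torque_reg_weight", 1.0e-3),
        )
        cost.normalization.m_max = np.broadcast_to(
            np.asarray(rc.get("m_max", 250.0), float), (5,)
        ).copy()
        phases = [
            PhaseSpec(
                index=p + 1,
                duration=float(reference_durations[p]),
                fixed_duration=fix_durations,
                n_intervals=int(oc.get("intervals_per_phase", [4, 4, 4])[p]),
            )
            for p in range(3)
        ]
        sv = oc.get("solver", {})
        return cls(
            variant=variant,
            cost=cost,
            phases=phases,
            friction_mu=float(oc.get("friction_mu", 0.8)),
            torque_limits=dict(oc.get("torque_limits", {})) or None
            or dict(hip=320.0, knee=320.0, ankle=250.0, shoulder=160.0, elbow=130.0),
            interaction_force_limit=float(oc.get("interaction_force_limit", 200.0)),
            interaction_moment_limit=float(oc.get("interaction_moment_limit", 60.0)),
            hand_moment_limit=float(oc.get("hand_moment_limit", 15.0)),
            duration_bounds=tuple(oc.get("phase_duration_bounds", (0.2, 3.0))),
            smoothness_weight=float(oc.get("smoothness_weight", 5.0e-5)),
            maxiter=int(sv.get("maxiter", 160)),
            ftol=float(sv.get("ftol", 1.0e-6)),
            eps=float(sv.get("eps", 1.0e-6)),
        )


@dataclass
class OCPSolution:
    """Solved (or best-feasible) trajectory optimization result."""

    spec: OCPSpec
    x: np.ndarray
    objective: float
    success: bool
    message: str
    n_iter: int
    max_violation: float
    ocp: "TranscribedOCP"

    def trajectory(self, samples_per_phase: int = 30) -> Trajectory:
        return self.ocp.resample(self.x, samples_per_phase)

    @property
    def durations(self) -> np.ndarray:
        return self.ocp.unpack(self.x)["durations"]


class TranscribedOCP:
    """The NLP form of one lifting OCP (see module docstring)."""

    def __init__(self, lm: LiftingModel, spec: OCPSpec, reference: ReferenceMotion):
        if spec.variant == "HwE" and not lm.with_exo:
            raise ValueError("HwE problem requires a model with the exoskeleton")
        if spec.variant == "HO" and lm.with_exo:
            raise ValueError("HO problem requires the human-only model")
        self.lm = lm
        self.spec = spec
        self.reference = reference
        self.rmap = ReducedMap(lm)
        self.with_exo = lm.with_exo

        Ns = [p.n_intervals for p in spec.phases]
        self.Ns = Ns
        self.K = sum(Ns) + 1  # knot count
        self.i1, self.i2 = Ns[0], Ns[0] + Ns[1]
        # per-phase knot index lists (boundary knots shared)
        self.phase_knots = [
            np.arange(0, self.i1 + 1),
            np.arange(self.i1, self.i2 + 1),
            np.arange(self.i2, self.K),
        ]
        # collocation samples: every knot plus every interval midpoint, so
        # the integrands and path constraints see twice the knot resolution
        self.n_per_phase = [2 * N + 1 for N in Ns]
        self.n_samples = sum(self.n_per_phase)
        self.sample_phase = np.concatenate(
            [np.full(n, p + 1) for p, n in enumerate(self.n_per_phase)]
        )
        pos: list[int] = []
        ofs = 0
        for p, N in enumerate(Ns):
            evens = ofs + np.arange(0, 2 * N + 1, 2)
            pos.extend(evens if p == 0 else evens[1:])
            ofs += 2 * N + 1
        self.knot_sample_pos = np.array(pos)  # K knot-coincident samples

        # fixed boundary poses: start/end at the reference standing pose
        self.zeta_start = reference.zeta_stand.copy()
        self.zeta_end = reference.zeta_stand.copy()
        self.handle_target = np.concatenate(
            [lm.box.rest_pose[:2] + lm.box.handle_local, [lm.hand_grasp_angle]]
        )
        mg = lm.box.mass * lm.model.gravity
        self.w_first = np.zeros(3)
        self.w_last = np.array([0.0, mg, 0.0])

        # variable packing
        self.free_durations = [not p.fixed_duration for p in spec.phases]
        n_zeta = (self.K - 2) * N_ZETA
        n_w = max(Ns[1] - 1, 0) * 3
        n_u = self.K if self.with_exo else 0
        n_T = sum(self.free_durations)
        self._off_zeta = 0
        self._off_w = n_zeta
        self._off_u = n_zeta + n_w
        self._off_T = n_zeta + n_w + n_u
        self.n_vars = n_zeta + n_w + n_u + n_T

        self.smoothness_weight = spec.smoothness_weight
        self._union_cs = self._build_union_constraints()
        self._lam_cols = self._build_lam_columns()
        self._tau_limits = np.array(
            [spec.torque_limits[j] for j in ("hip", "knee", "ankle", "shoulder", "elbow")]
        )
        self._cache: dict[bytes, dict] = {}
        self._track_ref = None
        if spec.cost.kind == "LSQ":
            self._track_ref = self._reference_human_q()

    # -- construction helpers ----------------------------------------

    def _build_union_constraints(self) -> ConstraintSet:
        """One constraint set holding every row any phase activates."""
        cs2 = self.lm.phase_constraints(2)  # feet, box_ground, hands_box, lumbar, exo
        return cs2

    def _build_lam_columns(self):
        """Per-phase selection of unknown multiplier rows in the union set."""
        cs = self._union_cs
        sel = {}
        for phase in (1, 2, 3):
            names = ["feet"]
            if phase in (1, 2):
                names.append("box_ground")
            if phase == 3:
                names.append("hands_box")
            names += [f"lumbar:{k}" for k in range(4)]
            if self.with_exo:
                names += ["exo_thigh", "exo_pelvis", "exo_trunk"]
            rows = np.concatenate([np.arange(cs.rows_of(n).start, cs.rows_of(n).stop) for n in names])
            sel[phase] = (names, rows)
        n0 = len(sel[1][1])
        assert all(len(v[1]) == n0 for v in sel.values())
        return sel

    def _reference_human_q(self) -> np.ndarray:
        """Reference human coordinates at the knot times (fixed durations)."""
        t = self._knot_times(np.array([p.duration for p in self.spec.phases]))
        zeta = self.reference.zeta(t)
        q = self.rmap.q(zeta, 1)
        return q[:, HUMAN_SLICE]

    def _knot_times(self, durations: np.ndarray) -> np.ndarray:
        t = [np.array([0.0])]
        t0 = 0.0
        for p, N in enumerate(self.Ns):
            seg = t0 + durations[p] * np.arange(1, N + 1) / N
            t.append(seg)
            t0 += durations[p]
        return np.concatenate(t)

    # -- packing ------------------------------------------------------

    def pack(self, zeta_knots: np.ndarray, w_knots: np.ndarray,
             u_knots: np.ndarray | None, durations: np.ndarray) -> np.ndarray:
        x = np.zeros(self.n_vars)
        x[self._off_zeta : self._off_w] = zeta_knots[1:-1].ravel()
        if self.Ns[1] > 1:
            x[self._off_w : self._off_u] = (w_knots[1:-1] / W_SCALE).ravel()
        if self.with_exo:
            x[self._off_u : self._off_T] = u_knots
        k = self._off_T
        for p in range(3):
            if self.free_durations[p]:
                x[k] = durations[p]
                k += 1
        return x

    def unpack(self, x: np.ndarray) -> dict:
        x = np.asarray(x, dtype=float)
        zeta = np.empty((self.K, N_ZETA))
        zeta[0] = self.zeta_start
        zeta[-1] = self.zeta_end
        zeta[1:-1] = x[self._off_zeta : self._off_w].reshape(self.K - 2, N_ZETA)
        nw = self.Ns[1] + 1
        w = np.empty((nw, 3))
        w[0] = self.w_first
        w[-1] = self.w_last
        if nw > 2:
            w[1:-1] = x[self._off_w : self._off_u].reshape(nw - 2, 3) * W_SCALE
        u = x[self._off_u : self._off_T] if self.with_exo else None
        durations = np.array([p.duration for p in self.spec.phases])
        k = self._off_T
        for p in range(3):
            if self.free_durations[p]:
                durations[p] = x[k]
                k += 1
        # guard against transient out-of-bound line-search points
        durations = np.clip(durations, 0.05, None)
        return dict(zeta=zeta, w=w, u=u, durations=durations)

    def bounds(self) -> list[tuple[float, float]]:
        b: list[tuple[float, float]] = []
        for _ in range(self.K - 2):
            b.extend([tuple(r) for r in ZETA_BOUNDS])
        for _ in range(max(self.Ns[1] - 1, 0)):
            b.extend([(-400 / W_SCALE[0], 400 / W_SCALE[0])] * 2 + [(-3.0, 3.0)])
        if self.with_exo:
            b.extend([(-1.0, 1.0)] * self.K)
        for p in range(3):
            if self.free_durations[p]:
                b.append(self.spec.duration_bounds)
        return b

    # -- evaluation ---------------------------------------------------

    def _evaluate(self, x: np.ndarray) -> dict:
        key = x.tobytes()
        hit = self._cache.get(key)
        if hit is not None:
            return hit
        v = self.unpack(x)
        zeta, w_knots, u_knots, durations = v["zeta"], v["w"], v["u"], v["durations"]
        t_knots = self._knot_times(durations)
        spline = CubicSpline(t_knots, zeta, bc_type="clamped")

        bounds = t_knots[[0, self.i1, self.i2, self.K - 1]]
        t_s = np.concatenate(
            [
                np.linspace(bounds[p], bounds[p + 1], self.n_per_phase[p])
                for p in range(3)
            ]
        )
        phases = self.sample_phase
        # states per phase with the phase-consistent coordinate map
        n = self.n_samples
        nq = self.lm.nq
        q = np.empty((n, nq))
        qd = np.empty((n, nq))
        qdd = np.empty((n, nq))
        for phase in (1, 2, 3):
            m = phases == phase
            tm = t_s[m]
            zm = spline(tm)
            zp = spline(tm + _H)
            zn = spline(tm - _H)
            qm = self.rmap.q(zm, phase)
            qp = self.rmap.q(zp, phase)
            qn = self.rmap.q(zn, phase)
            q[m] = qm
            qd[m] = (qp - qn) / (2 * _H)
            qdd[m] = (qp - 2 * qm + qn) / _H**2

        res = self._multi_phase_id(q, qd, qdd, phases, t_s, t_knots, w_knots, u_knots)
        # joint-range checks at interval midpoints (inter-node overshoot)
        z_mid = spline(0.5 * (t_knots[:-1] + t_knots[1:]))
        out = self._assemble(v, t_knots, t_s, q, qd, res, z_mid)
        if len(self._cache) > 4 * self.n_vars + 16:
            self._cache.pop(next(iter(self._cache)))
        self._cache[key] = out
        return out

    def _multi_phase_id(self, q, qd, qdd, phases, t_s, t_knots, w_knots, u_knots):
        """Batched inverse dynamics across all samples and phases."""
        lm = self.lm
        model = lm.model
        nq = lm.nq
        n = q.shape[0]
        cs = self._union_cs
        kin = model.kinematics(q)
        rates = model.rates(q, qd, kin)
        M = model.mass_matrix(q, kin)
        h = model.bias_forces(q, qd, kin, rates)
        rhs = np.einsum("nij,nj->ni", M, qdd) + h
        u_s = None
        if self.with_exo:
            rhs -= beam_generalized_force(model, q, lm.exo, kin)
            u_s = np.interp(t_s, t_knots, u_knots)
            hip = model.coord_index("pelvis_module")
            rhs[:, hip] -= lm.exo.actuator_max_torque * u_s

        G = cs.jacobian(q, kin)
        # hand wrench: piecewise-linear in the knot values on phase 2
        w_s = np.zeros((n, 3))
        m2 = phases == 2
        t2 = t_knots[self.phase_knots[1]]
        for k in range(3):
            w_s[m2, k] = np.interp(t_s[m2], t2, w_knots[:, k])
        Gh = G[:, cs.rows_of("hands_box"), :]
        rhs -= np.einsum("nij,ni->nj", Gh, w_s)

        d_lum = lm._lumbar_direction()
        joint_cols = list(JOINT_COORDS.values())
        A = np.zeros((n, nq, nq))
        for k, c in enumerate(joint_cols):
            A[:, c, k] = 1.0
        A[:, LUMBAR_COORDS, len(joint_cols)] = d_lum
        rows_idx = np.empty((n, nq - 6), dtype=int)
        for phase in (1, 2, 3):
            m = phases == phase
            rows_idx[m] = self._lam_cols[phase][1]
        Gsel = G[np.arange(n)[:, None], rows_idx, :]
        A[:, :, 6:] = np.swapaxes(Gsel, 1, 2)
        xsol = np.linalg.solve(A, rhs[..., None])[..., 0]

        tau = np.zeros((n, nq))
        for k, c in enumerate(joint_cols):
            tau[:, c] = xsol[:, k]
        lumbar_tau = xsol[:, 5][:, None] * d_lum
        tau[:, LUMBAR_COORDS] = lumbar_tau
        lam_flat = xsol[:, 6:]

        lam: dict[str, np.ndarray] = {}
        for name in ("feet", "box_ground", "hands_box", "lumbar:0", "lumbar:1",
                     "lumbar:2", "lumbar:3", "exo_thigh", "exo_pelvis", "exo_trunk"):
            if not cs.has(name):
                continue
            sl = cs.rows_of(name)
            width = sl.stop - sl.start
            arr = np.zeros((n, width))
            for phase in (1, 2, 3):
                names, rows = self._lam_cols[phase]
                m = phases == phase
                if name in names:
                    pos = np.searchsorted(rows, np.arange(sl.start, sl.stop))
                    if np.array_equal(rows[pos], np.arange(sl.start, sl.stop)):
                        arr[m] = lam_flat[m][:, pos]
            lam[name] = arr
        lam["hands_box"][m2] = w_s[m2]

        l5s1 = self._l5s1_batch(q, qd, qdd, kin, rates, phases, lam)
        return dict(tau=tau, lumbar_tau=lumbar_tau, lam=lam, l5s1=l5s1,
                    u=u_s, w=w_s, kin=kin, rates=rates)

    def _l5s1_batch(self, q, qd, qdd, kin, rates, phases, lam):
        lm = self.lm
        tmp = {"hands_box": lam["hands_box"]}
        if self.with_exo:
            tmp["exo_trunk"] = lam["exo_trunk"]
        # phase-wise because the airborne box joins the subtree in phase 3
        out = np.zeros(q.shape[0])
        for phase in (1, 2, 3):
            m = phases == phase
            if not m.any():
                continue
            sub_lam = {k: v[m] for k, v in tmp.items()}
            kin_m = [type(f)(f.theta[m], f.pos[m], f.jtheta[m], f.jpos[m]) for f in kin]
            rates_m = [
                type(r)(r.omega[m], r.vel[m], r.alpha0[m], r.acc0[m]) for r in rates
            ]
            out[m] = lm._l5s1_moment(
                q[m], qd[m], qdd[m], kin_m, phase, sub_lam, rates=rates_m
            )
        return out

    def _assemble(self, v, t_knots, t_s, q, qd, res, z_mid) -> dict:
        spec = self.spec
        cost = spec.cost
        phases = self.sample_phase
        lumbar_tau = res["lumbar_tau"]
        tau = res["tau"]
        lam = res["lam"]

        # trapezoid weights per phase over the (uniform) sample times
        wts = np.zeros(self.n_samples)
        ofs = 0
        for p, npts in enumerate(self.n_per_phase):
            dt = (t_s[ofs + npts - 1] - t_s[ofs]) / (npts - 1)
            wseg = np.full(npts, dt)
            wseg[0] = wseg[-1] = dt / 2
            wts[ofs : ofs + npts] = wseg
            ofs += npts

        # regularization on all joint torques (normalized)
        joint_cols = list(JOINT_COORDS.values())
        reg = np.sum((tau[:, joint_cols] / self._tau_limits) ** 2, axis=1)
        reg += np.sum((lumbar_tau / cost.normalization.m_max) ** 2, axis=1)
        J = cost.reg_weight * float(np.sum(wts * reg))
        if self.with_exo:
            J += cost.exo_weight * float(np.sum(wts * res["u"] ** 2))
        # small curvature penalty on the knot sequence: discourages
        # inter-node oscillation the collocation grid cannot see
        d2 = v["zeta"][2:] - 2 * v["zeta"][1:-1] + v["zeta"][:-2]
        J += self.smoothness_weight * float(np.sum(d2**2))

        if cost.kind == "LSQ":
            qh = q[self.knot_sample_pos][:, HUMAN_SLICE]
            J += cost.tracking_weight * float(np.sum((qh - self._track_ref) ** 2))
        else:
            integrand = {
                "CLBL": clbl_cost_integrand,
                "PLBL": plbl_cost_integrand,
                "HYB": hyb_cost_integrand,
            }[cost.kind](lumbar_tau, cost.normalization)
            J += float(np.sum(wts * integrand))

        # equality constraints
        eqs = []
        m2 = phases == 2
        hp = self._hand_pose_from_kin(res["kin"], m2)
        eqs.append((hp - self.handle_target).ravel())
        # zero hand-frame velocity at box touch (first phase-2 sample)
        i_touch = int(np.argmax(m2))
        eqs.append(self._hand_velocity(res["kin"], res["rates"], i_touch))
        eq = np.concatenate(eqs) if eqs else np.zeros(0)

        # inequality constraints (>= 0), all rows scaled to O(1)
        mu = spec.friction_mu
        ineqs = []
        f = lam["feet"] / _F0
        ineqs += [f[:, 1], mu * f[:, 1] - f[:, 0], mu * f[:, 1] + f[:, 0]]
        bg = lam["box_ground"] / _F0
        m12 = phases != 3
        ineqs.append(bg[m12, 1])
        hb = lam["hands_box"]
        m23 = phases != 1
        ineqs += [
            hb[m23, 1] / _F0,
            (mu * hb[m23, 1] - hb[m23, 0]) / _F0,
            (mu * hb[m23, 1] + hb[m23, 0]) / _F0,
            1.0 - hb[m23, 2] / spec.hand_moment_limit,
            1.0 + hb[m23, 2] / spec.hand_moment_limit,
        ]
        tl = self._tau_limits
        tj = tau[:, joint_cols] / tl
        ineqs += [(1.0 - tj).ravel(), (1.0 + tj).ravel()]
        lt = lumbar_tau / spec.cost.normalization.m_max
        ineqs += [(1.0 - lt).ravel(), (1.0 + lt).ravel()]
        if self.with_exo:
            fl, ml = spec.interaction_force_limit, spec.interaction_moment_limit
            for name in ("exo_thigh", "exo_pelvis", "exo_trunk"):
                arr = lam[name]
                lim = np.full(arr.shape[1], fl)
                if arr.shape[1] == 3:
                    lim[2] = ml
                sc = arr / lim
                ineqs += [(1.0 - sc).ravel(), (1.0 + sc).ravel()]
        # joint-range windows at interval midpoints (spline overshoot guard)
        ineqs += [
            (z_mid - ZETA_BOUNDS[:, 0]).ravel(),
            (ZETA_BOUNDS[:, 1] - z_mid).ravel(),
        ]
        ineq = np.concatenate(ineqs)

        viol = 0.0
        if eq.size:
            viol = max(viol, float(np.abs(eq).max()))
        if ineq.size:
            viol = max(viol, float(max(0.0, -ineq.min())))
        return dict(J=J, eq=eq, ineq=ineq, viol=viol, res=res, wts=wts,
                    t_knots=t_knots, q=q, qd=qd)

    def _hand_pose_from_kin(self, kin, mask) -> np.ndarray:
        lm = self.lm
        body = lm.body("forearm_hand")
        f = kin[body]
        from .multibody import apply_rot

        pos = f.pos[mask] + apply_rot(f.theta[mask], lm.grip_local)
        return np.concatenate([pos, f.theta[mask][:, None]], axis=-1)

    def _hand_velocity(self, kin, rates, i) -> np.ndarray:
        lm = self.lm
        body = lm.body("forearm_hand")
        f, r = kin[body], rates[body]
        from .multibody import apply_rot, perp

        rc = apply_rot(f.theta[i], lm.grip_local)
        vel = r.vel[i] + r.omega[i] * perp(rc)
        return np.array([vel[0], vel[1], r.omega[i]])

    # -- public NLP interface -----------------------------------------

    def objective(self, x: np.ndarray) -> float:
        return self._evaluate(np.asarray(x, float))["J"]

    def eq_constraints(self, x: np.ndarray) -> np.ndarray:
        return self._evaluate(np.asarray(x, float))["eq"]

    def ineq_constraints(self, x: np.ndarray) -> np.ndarray:
        return self._evaluate(np.asarray(x, float))["ineq"]

    def max_violation(self, x: np.ndarray) -> float:
        return self._evaluate(np.asarray(x, float))["viol"]

    # -- solution post-processing -------------------------------------

    def resample(self, x: np.ndarray, samples_per_phase: int = 30) -> Trajectory:
        """Dense trajectory (with torques, forces, L5/S1 series) at a solution."""
        v = self.unpack(x)
        t_knots = self._knot_times(v["durations"])
        spline = CubicSpline(t_knots, v["zeta"], bc_type="clamped")
        bounds = np.concatenate([[0.0], np.cumsum(v["durations"])])
        times, phases_l = [], []
        for p in range(3):
            tseg = np.linspace(bounds[p], bounds[p + 1], samples_per_phase)
            if p > 0:
                tseg = tseg[1:]
            times.append(tseg)
            phases_l.append(np.full(len(tseg), p + 1))
        t = np.concatenate(times)
        phases = np.concatenate(phases_l)
        nq = self.lm.nq
        n = len(t)
        q = np.empty((n, nq))
        qd = np.empty((n, nq))
        qdd = np.empty((n, nq))
        for phase in (1, 2, 3):
            m = phases == phase
            tm = t[m]
            zm, zp, zn = spline(tm), spline(tm + _H), spline(tm - _H)
            qm = self.rmap.q(zm, phase)
            q[m] = qm
            qd[m] = (self.rmap.q(zp, phase) - self.rmap.q(zn, phase)) / (2 * _H)
            qdd[m] = (self.rmap.q(zp, phase) - 2 * qm + self.rmap.q(zn, phase)) / _H**2
        # controls on the dense grid
        u_d = None
        if self.with_exo:
            u_spl = CubicSpline(t_knots, v["u"])
            u_d = np.clip(u_spl(t), -1.0, 1.0)
        w_d = np.zeros((n, 3))
        m2 = phases == 2
        t2 = t_knots[self.phase_knots[1]]
        for k in range(3):
            w_d[m2, k] = np.interp(t[m2], t2, v["w"][:, k])

        tau = np.zeros((n, nq))
        l5s1 = np.zeros(n)
        lam_store: dict[str, np.ndarray] = {}
        for phase in (1, 2, 3):
            m = phases == phase
            if not m.any():
                continue
            res = self.lm.inverse_dynamics(
                q[m], qd[m], qdd[m], phase,
                hand_wrench=w_d[m] if phase == 2 else None,
                u=u_d[m] if self.with_exo else None,
            )
            tau[m] = res.tau
            l5s1[m] = res.l5s1_moment
            for name, arr in res.lam.items():
                if name not in lam_store:
                    lam_store[name] = np.zeros((n, arr.shape[-1]))
                lam_store[name][m] = arr
        thL = self.rmap.zeta_from_q(q)[:, 3]
        extras = {"l5s1_moment": l5s1, "lumbar_flexion_deg": np.rad2deg(thL)}
        if u_d is not None:
            extras["u"] = u_d
            from .synthetic import _beam_extras

            extras.update(_beam_extras(self.lm, q))
        return Trajectory(time=t, q=q, qd=qd, qdd=qdd, tau=tau, phase=phases,
                          lam=lam_store, extras=extras)


def check_boundary_poses(ocp: TranscribedOCP) -> None:
    """Raise if the fixed start/end poses violate the phase-1 constraints."""
    for zeta, label in ((ocp.zeta_start, "initial"), (ocp.zeta_end, "final")):
        qb = ocp.rmap.q(zeta, 1)
        r = ocp.lm.phase_constraints(1).residual(qb)
        if np.abs(r).max() > 1e-8:
            raise ValueError(f"{label} boundary pose violates phase-1 constraints")


def build_ocp(
    lm: LiftingModel, spec: OCPSpec, reference: ReferenceMotion
) -> TranscribedOCP:
    """Transcribe the three-phase OCP for one model variant and cost."""
    ocp = TranscribedOCP(lm, spec, reference)
    # infeasible boundary poses are caught here, before any solve
    check_boundary_poses(ocp)
    return ocp


def initial_guess_from_reference(
    ocp: TranscribedOCP,
    reference: ReferenceMotion | None = None,
    from_solution: OCPSolution | None = None,
) -> np.ndarray:
    """Interpolate knot states/controls from the reference or a prior solution."""
    if from_solution is not None:
        src = from_solution.ocp.unpack(from_solution.x)
        return ocp.pack(src["zeta"], src["w"],
                        src["u"] if ocp.with_exo else None, src["durations"])
    reference = reference or ocp.reference
    durations = reference.durations.copy()
    t_knots = ocp._knot_times(durations)
    zeta = reference.zeta(t_knots)
    t2 = t_knots[ocp.phase_knots[1]]
    w = reference.hand_wrench(t2)
    u = np.zeros(ocp.K) if ocp.with_exo else None
    return ocp.pack(zeta, w, u, durations)


def solve_ocp(
    ocp: TranscribedOCP,
    x0: np.ndarray | None = None,
    candidates: tuple[np.ndarray, ...] = (),
) -> OCPSolution:
    """Solve the transcribed NLP with SLSQP plus a best-feasible safeguard.

    ``candidates`` are additional points (e.g. a feasible tracking
    solution) entered into the best-feasible bookkeeping before the
    solve, so the returned solution can never be worse than any of them.
    """
    if x0 is None:
        x0 = initial_guess_from_reference(ocp)
    x0 = np.asarray(x0, dtype=float)
    spec = ocp.spec
    best = {"x": None, "J": np.inf}

    def fun(x):
        out = ocp._evaluate(np.asarray(x, float))
        if out["viol"] <= FEAS_TOL and out["J"] < best["J"]:
            best["J"] = out["J"]
            best["x"] = np.array(x, dtype=float)
        return out["J"]

    for c in candidates:
        fun(np.asarray(c, dtype=float))

    cons = [
        {"type": "eq", "fun": ocp.eq_constraints},
        {"type": "ineq", "fun": ocp.ineq_constraints},
    ]
    res = minimize(
        fun,
        x0,
        method="SLSQP",
        bounds=ocp.bounds(),
        constraints=cons,
        options={"maxiter": spec.maxiter, "ftol": spec.ftol, "eps": spec.eps},
    )
    x_fin = np.asarray(res.x, dtype=float)
    fin = ocp._evaluate(x_fin)
    if fin["viol"] <= FEAS_TOL and fin["J"] < best["J"]:
        best["J"], best["x"] = fin["J"], x_fin
    if best["x"] is None:
        # no feasible iterate seen: report the failure with diagnostics
        return OCPSolution(
            spec=spec, x=x_fin, objective=float(fin["J"]), success=False,
            message=f"no feasible iterate (worst violation {fin['viol']:.3g}): "
            + res.message,
            n_iter=int(res.get("nit", -1)), max_violation=float(fin["viol"]), ocp=ocp,
        )
    xb = best["x"]
    outb = ocp._evaluate(xb)
    return OCPSolution(
        spec=spec,
        x=xb,
        objective=float(outb["J"]),
        success=True,
        message=str(res.message),
        n_iter=int(res.get("nit", -1)),
        max_violation=float(outb["viol"]),
        ocp=ocp,
    )
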