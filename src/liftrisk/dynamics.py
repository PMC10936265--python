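"""Constrained multibody dynamics.

Holonomic constraints (welds, point contacts, linear joint couplings) are
kept as explicit rows with residual g(q), Jacobian G(q) and the
acceleration bias Gdot(q, qd) qd needed for index-1 reduction.  Forward
dynamics solves the KKT system

    [ M  -G^T ] [qdd]   [ Q - h ]
    [ G   0   ] [lam] = [  b    ]

with Baumgarte-stabilized constraint right-hand side
b = -Gdot qd - 2 alpha (G qd) - beta^2 g.  Inverse dynamics solves the
square system for joint torques and multipliers; the redundancy of the
coupled lumbar torques is resolved by the minimum-normalized-torque rule
(see :mod:`liftrisk.lumbar`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp

from .multibody import MultibodyModel, FrameKinematics, FrameRates


class SingularConstraintError(RuntimeError):
    """KKT matrix singular: lists the (near-)dependent constraint rows."""

    def __init__(self, labels: list[str]):
        self.labels = labels
        super().__init__(
            "singular constraint system; dependent rows involve: " + ", ".join(labels)
        )


@dataclass
class PointConstraint:
    """Coincidence of a point on body_a with a point on body_b (or world)."""

    name: str
    body_a: int
    local_a: np.ndarray
    body_b: int | None = None
    local_b: np.ndarray | None = None
    target: np.ndarray | None = None  # world target when body_b is None

    rows: int = field(default=2, init=False)

    def __post_init__(self) -> None:
        self.local_a = np.asarray(self.local_a, dtype=float)
        if self.body_b is None:
            self.target = np.zeros(2) if self.target is None else np.asarray(self.target, float)
        else:
            self.local_b = np.asarray(self.local_b, dtype=float)

    def labels(self) -> list[str]:
        return [f"{self.name}:x", f"{self.name}:z"]


@dataclass
class WeldConstraint(PointConstraint):
    """Point coincidence plus relative-orientation lock (3 rows)."""

    rel_angle: float = 0.0
    target_angle: float = 0.0  # world angle of body_a when body_b is None

    def __post_init__(self) -> None:
        super().__post_init__()
        self.rows = 3

    def labels(self) -> list[str]:
        return [f"{self.name}:x", f"{self.name}:z", f"{self.name}:th"]


@dataclass
class LinearCoupling:
    """A single linear row a^T q = b (constant Jacobian)."""

    name: str
    coeffs: np.ndarray
    offset: float = 0.0

    rows: int = field(default=1, init=False)

    def __post_init__(self) -> None:
        self.coeffs = np.asarray(self.coeffs, dtype=float)

    def labels(self) -> list[str]:
        return [self.name]


Constraint = PointConstraint | LinearCoupling


class ConstraintSet:
    """An ordered collection of active constraint rows for one model."""

    def __init__(self, model: MultibodyModel, items: list[Constraint]):
        self.model = model
        self.items = list(items)
        self.n_rows = sum(it.rows for it in self.items)
        self.row_labels: list[str] = []
        self._slices: dict[str, slice] = {}
        n = 0
        for it in self.items:
            self.row_labels.extend(it.labels())
            self._slices[it.name] = slice(n, n + it.rows)
            n += it.rows

    def rows_of(self, name: str) -> slice:
        return self._slices[name]

    def summary(self) -> str:
        """Human-readable listing of the active rows (debugging aid)."""
        lines = [f"{self.n_rows} constraint rows:"]
        for it in self.items:
            kind = type(it).__name__
            lines.append(f"  {it.name:<12s} {kind:<16s} rows {self._slices[it.name]}")
        return "\n".join(lines)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"<ConstraintSet {self.names()}>"

    def names(self) -> list[str]:
        return [it.name for it in self.items]

    def has(self, name: str) -> bool:
        return name in self._slices

    def residual(self, q: np.ndarray, kin: list[FrameKinematics] | None = None) -> np.ndarray:
        q = np.asarray(q, dtype=float)
        if kin is None:
            kin = self.model.kinematics(q)
        out = np.zeros(q.shape[:-1] + (self.n_rows,))
        n = 0
        for it in self.items:
            if isinstance(it, LinearCoupling):
                out[..., n] = np.einsum("...i,i->...", q, it.coeffs) - it.offset
            else:
                pa, _ = self.model.point_kinematics(kin, it.body_a, it.local_a)
                if it.body_b is None:
                    g = pa - it.target
                    if isinstance(it, WeldConstraint):
                        gth = kin[it.body_a].theta - it.target_angle
                else:
                    pb, _ = self.model.point_kinematics(kin, it.body_b, it.local_b)
                    g = pa - pb
                    if isinstance(it, WeldConstraint):
                        gth = kin[it.body_a].theta - kin[it.body_b].theta - it.rel_angle
                out[..., n : n + 2] = g
                if isinstance(it, WeldConstraint):
                    out[..., n + 2] = gth
            n += it.rows
        return out

    def jacobian(self, q: np.ndarray, kin: list[FrameKinematics] | None = None) -> np.ndarray:
        q = np.asarray(q, dtype=float)
        if kin is None:
            kin = self.model.kinematics(q)
        G = np.zeros(q.shape[:-1] + (self.n_rows, self.model.nq))
        n = 0
        for it in self.items:
            if isinstance(it, LinearCoupling):
                G[..., n, :] = it.coeffs
            else:
                _, ja = self.model.point_kinematics(kin, it.body_a, it.local_a)
                if it.body_b is None:
                    G[..., n : n + 2, :] = ja
                    if isinstance(it, WeldConstraint):
                        G[..., n + 2, :] = kin[it.body_a].jtheta
                else:
                    _, jb = self.model.point_kinematics(kin, it.body_b, it.local_b)
                    G[..., n : n + 2, :] = ja - jb
                    if isinstance(it, WeldConstraint):
                        G[..., n + 2, :] = kin[it.body_a].jtheta - kin[it.body_b].jtheta
            n += it.rows
        return G

    def accel_bias(
        self,
        q: np.ndarray,
        qd: np.ndarray,
        kin: list[FrameKinematics] | None = None,
        rates: list[FrameRates] | None = None,
    ) -> np.ndarray:
        """Gdot(q, qd) qd per row (zero-qdd constraint acceleration)."""
        q = np.asarray(q, dtype=float)
        if kin is None:
            kin = self.model.kinematics(q)
        if rates is None:
            rates = self.model.rates(q, qd, kin)
        out = np.zeros(q.shape[:-1] + (self.n_rows,))
        n = 0
        for it in self.items:
            if isinstance(it, LinearCoupling):
                pass  # constant Jacobian
            else:
                _, aa = self.model.point_rates(kin, rates, it.body_a, it.local_a)
                if it.body_b is None:
                    out[..., n : n + 2] = aa
                    if isinstance(it, WeldConstraint):
                        out[..., n + 2] = rates[it.body_a].alpha0
                else:
                    _, ab = self.model.point_rates(kin, rates, it.body_b, it.local_b)
                    out[..., n : n + 2] = aa - ab
                    if isinstance(it, WeldConstraint):
                        out[..., n + 2] = rates[it.body_a].alpha0 - rates[it.body_b].alpha0
            n += it.rows
        return out


def forward_dynamics(
    model: MultibodyModel,
    q: np.ndarray,
    qd: np.ndarray,
    Q: np.ndarray,
    constraints: ConstraintSet | None = None,
    baumgarte: tuple[float, float] = (10.0, 25.0),
) -> tuple[np.ndarray, np.ndarray]:
    """Constrained accelerations and multipliers.

    Parameters
    ----------
    Q : generalized applied force, shape (..., nq).
    baumgarte : (2*alpha, beta^2) stabilization gains.

    Returns (qdd, lam) with lam per active constraint row.
    """
    q = np.asarray(q, dtype=float)
    qd = np.asarray(qd, dtype=float)
    kin = model.kinematics(q)
    M = model.mass_matrix(q, kin)
    h = model.bias_forces(q, qd, kin)
    rhs_top = np.asarray(Q, dtype=float) - h
    if constraints is None or constraints.n_rows == 0:
        return np.linalg.solve(M, rhs_top), np.zeros(q.shape[:-1] + (0,))
    rates = model.rates(q, qd, kin)
    G = constraints.jacobian(q, kin)
    s = np.linalg.svd(G, compute_uv=False)
    if np.any(s[..., -1] < 1e-10 * s[..., 0]):
        raise SingularConstraintError(_dependent_rows(G, constraints))
    g = constraints.residual(q, kin)
    gdqd = constraints.accel_bias(q, qd, kin, rates)
    two_alpha, beta2 = baumgarte
    b = -gdqd - two_alpha * np.einsum("...ij,...j->...i", G, qd) - beta2 * g
    m = constraints.n_rows
    nq = model.nq
    kkt = np.zeros(q.shape[:-1] + (nq + m, nq + m))
    kkt[..., :nq, :nq] = M
    kkt[..., :nq, nq:] = -np.swapaxes(G, -1, -2)
    kkt[..., nq:, :nq] = G
    rhs = np.concatenate([rhs_top, b], axis=-1)
    try:
        sol = np.linalg.solve(kkt, rhs)
    except np.linalg.LinAlgError:
        raise SingularConstraintError(_dependent_rows(G, constraints)) from None
    resid = np.einsum("...ij,...j->...i", kkt, sol) - rhs
    scale = 1.0 + np.abs(rhs).max()
    if not np.all(np.isfinite(sol)) or np.abs(resid).max() > 1e-6 * scale:
        raise SingularConstraintError(_dependent_rows(G, constraints))
    return sol[..., :nq], sol[..., nq:]


def _dependent_rows(G: np.ndarray, constraints: ConstraintSet) -> list[str]:
    """Diagnose which rows make G rank deficient (first batch element)."""
    Gm = G.reshape((-1,) + G.shape[-2:])[0]
    u, s, vt = np.linalg.svd(Gm)
    tol = max(Gm.shape) * np.finfo(float).eps * (s[0] if s.size else 1.0)
    null_left = u[:, s < tol] if s.size else u
    involved = np.where(np.abs(null_left).max(axis=1) > 1e-8)[0] if null_left.size else []
    return [constraints.row_labels[i] for i in involved] or constraints.row_labels


def simulate(
    model: MultibodyModel,
    constraints: ConstraintSet | None,
    q0: np.ndarray,
    qd0: np.ndarray,
    t_span: tuple[float, float],
    applied_force=None,
    baumgarte: tuple[float, float] = (10.0, 25.0),
    rtol: float = 1e-8,
    atol: float = 1e-10,
    t_eval=None,
):
    """Integrate the constrained dynamics with adaptive Runge-Kutta.

    ``applied_force(t, q, qd)`` returns the generalized force (default 0).
    """
    nq = model.nq

    def rhs(t, y):
        q, qd = y[:nq], y[nq:]
        Q = np.zeros(nq) if applied_force is None else applied_force(t, q, qd)
        qdd, _ = forward_dynamics(model, q, qd, Q, constraints, baumgarte)
        return np.concatenate([qd, qdd])

    y0 = np.concatenate([np.asarray(q0, float), np.asarray(qd0, float)])
    sol = solve_ivp(rhs, t_span, y0, method="RK45", rtol=rtol, atol=atol, t_eval=t_eval)
    if not sol.success:
        raise RuntimeError(f"integration failed: {sol.message}")
    return sol
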