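"""Independent reference implementations used by several test modules.

These are deliberately written against the underlying physics (finite
elements, symbolic Lagrangian mechanics) rather than against the package
code, so they can serve as oracles for it.
"""

import numpy as np


def euler_bernoulli_fem(L, deltaL, EI, n_el=100):
    """FEM cantilever with a prescribed transverse tip deflection.

    Hermite beam elements; clamped root, tip displacement imposed with
    free tip rotation (roller-style support).  Returns (s_nodes,
    deflection, tip shear, root moment).
    """
    le = L / n_el
    k = (EI / le**3) * np.array(
        [
            [12, 6 * le, -12, 6 * le],
            [6 * le, 4 * le**2, -6 * le, 2 * le**2],
            [-12, -6 * le, 12, -6 * le],
            [6 * le, 2 * le**2, -6 * le, 4 * le**2],
        ]
    )
    ndof = 2 * (n_el + 1)
    K = np.zeros((ndof, ndof))
    for e in range(n_el):
        i = 2 * e
        K[i : i + 4, i : i + 4] += k
    fixed = {0: 0.0, 1: 0.0, ndof - 2: deltaL}
    free = [i for i in range(ndof) if i not in fixed]
    F = np.zeros(ndof)
    rhs = F[free] - K[np.ix_(free, list(fixed))] @ np.array(list(fixed.values()))
    d = np.zeros(ndof)
    d[free] = np.linalg.solve(K[np.ix_(free, free)], rhs)
    for i, v in fixed.items():
        d[i] = v
    react = K @ d - F
    tip_shear = react[ndof - 2]
    root_moment = react[1]
    return np.linspace(0, 1, n_el + 1), d[0::2], tip_shear, root_moment


# double-pendulum parameters shared between the engine model and the oracle
PEND = dict(L1=0.8, L2=0.6, M1=2.0, M2=1.5, C1=0.35, C2=0.25, I1=0.05, I2=0.03,
            GRAV=9.81)


def double_pendulum_model():
    """The engine-side two-link chain (hanging-segment convention)."""
    from liftrisk.multibody import REVOLUTE, Body, MultibodyModel

    p = PEND
    bodies = [
        Body("link1", REVOLUTE, -1, anchor=[0.0, 0.0], mass=p["M1"],
             com=[0.0, -p["C1"]], inertia=p["I1"]),
        Body("link2", REVOLUTE, 0, anchor=[0.0, -p["L1"]], mass=p["M2"],
             com=[0.0, -p["C2"]], inertia=p["I2"]),
    ]
    return MultibodyModel(bodies, gravity=p["GRAV"])


def double_pendulum_oracle():
    """Closed-form accelerations from an independent Lagrangian derivation."""
    import sympy as sp

    p = PEND
    t = sp.symbols("t")
    q1, q2 = sp.Function("q1")(t), sp.Function("q2")(t)
    th1, th2 = q1, q1 + q2
    p1 = sp.Matrix([p["C1"] * sp.sin(th1), -p["C1"] * sp.cos(th1)])
    pj = sp.Matrix([p["L1"] * sp.sin(th1), -p["L1"] * sp.cos(th1)])
    p2 = pj + sp.Matrix([p["C2"] * sp.sin(th2), -p["C2"] * sp.cos(th2)])
    v1, v2 = p1.diff(t), p2.diff(t)
    T = (
        p["M1"] * (v1.T * v1)[0] / 2
        + p["M2"] * (v2.T * v2)[0] / 2
        + p["I1"] * sp.diff(th1, t) ** 2 / 2
        + p["I2"] * sp.diff(th2, t) ** 2 / 2
    )
    V = p["GRAV"] * (p["M1"] * p1[1] + p["M2"] * p2[1])
    Lag = sp.simplify(T - V)
    qs = [q1, q2]
    qd = [sp.diff(q, t) for q in qs]
    qdd = [sp.diff(q, t, 2) for q in qs]
    eqs = [sp.diff(sp.diff(Lag, qd[i]), t) - sp.diff(Lag, qs[i]) for i in range(2)]
    tau1, tau2 = sp.symbols("tau1 tau2")
    sol = sp.solve([sp.Eq(eqs[0], tau1), sp.Eq(eqs[1], tau2)], qdd, dict=True)[0]
    syms = (qs[0], qs[1], qd[0], qd[1], tau1, tau2)
    return sp.lambdify(syms, [sp.simplify(sol[qdd[0]]), sp.simplify(sol[qdd[1]])])
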