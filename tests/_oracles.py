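"""Independent symbolic oracles used by the test suite.

The rigid-body oracle derives the equations of motion of the serial arm from
the Lagrangian with sympy (kinetic + potential energy, Euler-Lagrange via
chain rule, generalized external force J^T F) and lambdifies them; it shares
no code with the recursive Newton-Euler implementation it checks. The
plasticity oracle evaluates the printed learning-rule formulas in 50-digit
arithmetic.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np
import sympy as sp


def _rot(axis, q):
    K = sp.Matrix([[0, -axis[2], axis[1]],
                   [axis[2], 0, -axis[0]],
                   [-axis[1], axis[0], 0]])
    return sp.eye(3) + sp.sin(q) * K + (1 - sp.cos(q)) * (K * K)


def _as_key(*arrays):
    return tuple(tuple(np.asarray(a, dtype=float).ravel()) for a in arrays)


@lru_cache(maxsize=8)
def _lagrangian_cached(n_links, axes_k, offs_k, coms_k, masses_k, inert_k, grav_k, ee_k):
    q = sp.Matrix(sp.symbols(f"q:{n_links}"))
    qd = sp.Matrix(sp.symbols(f"qd:{n_links}"))
    qdd = sp.Matrix(sp.symbols(f"qdd:{n_links}"))
    Fs = sp.Matrix(sp.symbols("F0:3"))

    def num(flat, shape):
        return np.array(flat, dtype=float).reshape(shape)

    axes = num(axes_k, (n_links, 3))
    offs = num(offs_k, (n_links, 3))
    coms = num(coms_k, (n_links, 3))
    masses = num(masses_k, (n_links,))
    inert = num(inert_k, (n_links, 3, 3))
    grav = sp.Matrix(num(grav_k, (3,)))
    ee = sp.Matrix(num(ee_k, (3,)))

    R = sp.eye(3)
    o = sp.zeros(3, 1)
    om = sp.zeros(3, 1)
    T = sp.S.Zero
    V = sp.S.Zero
    for i in range(n_links):
        a_w = R * sp.Matrix(axes[i])
        o = o + R * sp.Matrix(offs[i])
        om = om + a_w * qd[i]
        R = R * _rot(sp.Matrix(axes[i]), q[i])
        c_w = o + R * sp.Matrix(coms[i])
        # COM velocity: differentiate c_w along the trajectory
        v_c = sp.zeros(3, 1)
        for j in range(n_links):
            v_c += c_w.diff(q[j]) * qd[j]
        Iw = R * sp.Matrix(inert[i]) * R.T
        T += (masses[i] * (v_c.T * v_c)[0] + (om.T * Iw * om)[0]) / 2
        V += -masses[i] * (grav.T * c_w)[0]
    p_ee = o + R * ee

    L = T - V
    tau = []
    for i in range(n_links):
        dLdqd = L.diff(qd[i])
        ddt = sp.S.Zero
        for j in range(n_links):
            ddt += dLdqd.diff(q[j]) * qd[j] + dLdqd.diff(qd[j]) * qdd[j]
        gen = ddt - L.diff(q[i])
        # external end-effector force enters as J^T F on the right-hand side
        J_col = p_ee.diff(q[i])
        gen -= (J_col.T * Fs)[0]
        tau.append(gen)

    args = list(q) + list(qd) + list(qdd) + list(Fs)
    f = sp.lambdify(args, tau, modules="numpy", cse=True)

    def torque(qv, qdv, qddv, fext):
        return np.array(f(*qv, *qdv, *qddv, *fext), dtype=float)

    return torque


def lagrangian_torque_fn(axes, offs, coms, masses, inert, grav, ee):
    """Independent Euler-Lagrange torque oracle for a specific chain.

    Returns ``torque(q, qd, qdd, fext)`` for the chain whose (numeric) link
    parameters are given; ``n_links`` is inferred from the arrays.
    """
    n_links = len(np.asarray(masses))
    return _lagrangian_cached(
        n_links, *_as_key(axes, offs, coms, masses, inert, grav, ee))


def plasticity_rule_exact(rule: str, digits: int = 50, alpha: int = 1000, **kw):
    """Printed learning-rule formulas in ``digits``-digit arithmetic."""
    a = sp.Integer(alpha)

    def R(x):
        return sp.Rational(str(x))

    if rule == "decay_pow":
        expr = 1 / (R(kw["x"]) + 1) ** a
    elif rule == "pf_pc":
        expr = R(kw["ltp"]) / (R(kw["io"]) + 1) ** a - R(kw["ltd"]) * R(kw["io"])
    elif rule == "mf_dcn":
        expr = R(kw["ltp"]) / (R(kw["pc"]) + 1) ** a - R(kw["ltd"]) * R(kw["pc"])
    elif rule == "pc_dcn":
        expr = (R(kw["ltp"]) * R(kw["pc"]) ** a
                * (1 - 1 / (R(kw["dcn"]) + 1) ** a)
                - R(kw["ltd"]) * (1 - R(kw["pc"])))
    elif rule == "io_dcn":
        expr = R(kw["mtp"]) * R(kw["io"]) - R(kw["mtd"]) / (R(kw["io"]) + 1) ** a
    else:
        raise ValueError(rule)
    return float(sp.N(expr, digits))
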