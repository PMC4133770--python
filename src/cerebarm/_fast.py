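"""Numba-jitted numerical kernels.

Everything here is an implementation detail of :mod:`cerebarm.arm` and
:mod:`cerebarm.control`: recursive Newton-Euler inverse dynamics, forward
dynamics, the fixed-step RK4 plant integrator, and a fused per-trial loop
(network -> torque -> plant -> error -> plasticity) used by the experiment
driver. The fused loop repeats, operation for operation, the pure-Python
modular path (`cerebarm.control.run_trial_reference`); the test suite asserts
their equivalence.

Link parameters arrive packed as plain float64 arrays (payload already folded
into the last link as a composite rigid body):

* ``axes (3,3)``   unit joint axes, each in its parent link frame
* ``offs (3,3)``   position of joint i in the parent link frame
* ``coms (3,3)``   link centre of mass in the link's own frame
* ``masses (3,)``, ``inert (3,3,3)`` inertia tensors about the COM, link frame
* ``grav (3,)``    gravity vector in the base frame
* ``ee (3,)``      end-effector point in the last link frame

The inner loops are written in explicit scalar form (no BLAS calls, no
temporary arrays) because they execute tens of millions of times per
experiment.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def _rot_axis_into(axis, q, R):
    """Rodrigues rotation about a unit axis, written into R."""
    c = np.cos(q)
    s = np.sin(q)
    v = 1.0 - c
    x, y, z = axis[0], axis[1], axis[2]
    R[0, 0] = c + x * x * v
    R[0, 1] = x * y * v - z * s
    R[0, 2] = x * z * v + y * s
    R[1, 0] = y * x * v + z * s
    R[1, 1] = c + y * y * v
    R[1, 2] = y * z * v - x * s
    R[2, 0] = z * x * v - y * s
    R[2, 1] = z * y * v + x * s
    R[2, 2] = c + z * z * v


@njit(cache=True)
def _outward_kinematics(q, qd, qdd, axes, offs, coms, inert, grav,
                        Rw, aw, om, al, o, ao, cw, ac, Iw):
    """Outward Newton-Euler pass; fills the per-link world-frame arrays.

    Gravity enters through the standard trick of accelerating the base by
    -grav, so COM accelerations already contain the gravitational term.
    """
    Rloc = np.empty((3, 3))
    # base "previous link" state
    Rp = np.eye(3)
    omp = np.zeros(3)
    alp = np.zeros(3)
    op = np.zeros(3)
    aop = np.empty(3)
    for r in range(3):
        aop[r] = -grav[r]

    for i in range(3):
        # world joint axis and joint origin offset
        a0 = Rp[0, 0] * axes[i, 0] + Rp[0, 1] * axes[i, 1] + Rp[0, 2] * axes[i, 2]
        a1 = Rp[1, 0] * axes[i, 0] + Rp[1, 1] * axes[i, 1] + Rp[1, 2] * axes[i, 2]
        a2 = Rp[2, 0] * axes[i, 0] + Rp[2, 1] * axes[i, 1] + Rp[2, 2] * axes[i, 2]
        r0 = Rp[0, 0] * offs[i, 0] + Rp[0, 1] * offs[i, 1] + Rp[0, 2] * offs[i, 2]
        r1 = Rp[1, 0] * offs[i, 0] + Rp[1, 1] * offs[i, 1] + Rp[1, 2] * offs[i, 2]
        r2 = Rp[2, 0] * offs[i, 0] + Rp[2, 1] * offs[i, 1] + Rp[2, 2] * offs[i, 2]
        aw[i, 0] = a0
        aw[i, 1] = a1
        aw[i, 2] = a2
        o[i, 0] = op[0] + r0
        o[i, 1] = op[1] + r1
        o[i, 2] = op[2] + r2

        # acceleration of the joint origin:
        # ao = aop + alp x r + omp x (omp x r)
        wxr0 = omp[1] * r2 - omp[2] * r1
        wxr1 = omp[2] * r0 - omp[0] * r2
        wxr2 = omp[0] * r1 - omp[1] * r0
        ao[i, 0] = aop[0] + (alp[1] * r2 - alp[2] * r1) + (omp[1] * wxr2 - omp[2] * wxr1)
        ao[i, 1] = aop[1] + (alp[2] * r0 - alp[0] * r2) + (omp[2] * wxr0 - omp[0] * wxr2)
        ao[i, 2] = aop[2] + (alp[0] * r1 - alp[1] * r0) + (omp[0] * wxr1 - omp[1] * wxr0)

        # angular velocity / acceleration
        om[i, 0] = omp[0] + a0 * qd[i]
        om[i, 1] = omp[1] + a1 * qd[i]
        om[i, 2] = omp[2] + a2 * qd[i]
        al[i, 0] = alp[0] + a0 * qdd[i] + (omp[1] * a2 - omp[2] * a1) * qd[i]
        al[i, 1] = alp[1] + a1 * qdd[i] + (omp[2] * a0 - omp[0] * a2) * qd[i]
        al[i, 2] = alp[2] + a2 * qdd[i] + (omp[0] * a1 - omp[1] * a0) * qd[i]

        # world orientation of the link
        _rot_axis_into(axes[i], q[i], Rloc)
        for r in range(3):
            for c in range(3):
                s = 0.0
                for k in range(3):
                    s += Rp[r, k] * Rloc[k, c]
                Rw[i, r, c] = s

        # COM position and acceleration
        rc0 = Rw[i, 0, 0] * coms[i, 0] + Rw[i, 0, 1] * coms[i, 1] + Rw[i, 0, 2] * coms[i, 2]
        rc1 = Rw[i, 1, 0] * coms[i, 0] + Rw[i, 1, 1] * coms[i, 1] + Rw[i, 1, 2] * coms[i, 2]
        rc2 = Rw[i, 2, 0] * coms[i, 0] + Rw[i, 2, 1] * coms[i, 1] + Rw[i, 2, 2] * coms[i, 2]
        cw[i, 0] = o[i, 0] + rc0
        cw[i, 1] = o[i, 1] + rc1
        cw[i, 2] = o[i, 2] + rc2
        wxc0 = om[i, 1] * rc2 - om[i, 2] * rc1
        wxc1 = om[i, 2] * rc0 - om[i, 0] * rc2
        wxc2 = om[i, 0] * rc1 - om[i, 1] * rc0
        ac[i, 0] = ao[i, 0] + (al[i, 1] * rc2 - al[i, 2] * rc1) + (om[i, 1] * wxc2 - om[i, 2] * wxc1)
        ac[i, 1] = ao[i, 1] + (al[i, 2] * rc0 - al[i, 0] * rc2) + (om[i, 2] * wxc0 - om[i, 0] * wxc2)
        ac[i, 2] = ao[i, 2] + (al[i, 0] * rc1 - al[i, 1] * rc0) + (om[i, 0] * wxc1 - om[i, 1] * wxc0)

        # world inertia about the COM: Iw = R I R^T
        for r in range(3):
            t0 = inert[i, 0, 0] * Rw[i, r, 0] + inert[i, 1, 0] * Rw[i, r, 1] + inert[i, 2, 0] * Rw[i, r, 2]
            t1 = inert[i, 0, 1] * Rw[i, r, 0] + inert[i, 1, 1] * Rw[i, r, 1] + inert[i, 2, 1] * Rw[i, r, 2]
            t2 = inert[i, 0, 2] * Rw[i, r, 0] + inert[i, 1, 2] * Rw[i, r, 1] + inert[i, 2, 2] * Rw[i, r, 2]
            for c in range(3):
                Iw[i, r, c] = t0 * Rw[i, c, 0] + t1 * Rw[i, c, 1] + t2 * Rw[i, c, 2]

        Rp = Rw[i]
        omp = om[i]
        alp = al[i]
        op = o[i]
        aop = ao[i]


@njit(cache=True)
def rne(q, qd, qdd, axes, offs, coms, masses, inert, grav, ee, fext):
    """Recursive Newton-Euler inverse dynamics in base-frame coordinates.

    Returns the joint torques that realize (q, qd, qdd) under gravity with
    the external force ``fext`` (base frame) applied at the end-effector
    point of the last link.
    """
    Rw = np.empty((3, 3, 3))
    aw = np.empty((3, 3))
    om = np.empty((3, 3))
    al = np.empty((3, 3))
    o = np.empty((3, 3))
    ao = np.empty((3, 3))
    cw = np.empty((3, 3))
    ac = np.empty((3, 3))
    Iw = np.empty((3, 3, 3))
    _outward_kinematics(q, qd, qdd, axes, offs, coms, inert, grav,
                        Rw, aw, om, al, o, ao, cw, ac, Iw)

    tau = np.empty(3)
    fn0 = fn1 = fn2 = 0.0      # force passed up from the child
    nn0 = nn1 = nn2 = 0.0      # moment passed up from the child
    on0 = on1 = on2 = 0.0      # child joint origin
    for i in range(2, -1, -1):
        # Newton: inertial force of the link
        F0 = masses[i] * ac[i, 0]
        F1 = masses[i] * ac[i, 1]
        F2 = masses[i] * ac[i, 2]
        # Euler about the COM: N = Iw*al + om x (Iw*om)
        Iw0 = Iw[i, 0, 0] * om[i, 0] + Iw[i, 0, 1] * om[i, 1] + Iw[i, 0, 2] * om[i, 2]
        Iw1 = Iw[i, 1, 0] * om[i, 0] + Iw[i, 1, 1] * om[i, 1] + Iw[i, 1, 2] * om[i, 2]
        Iw2 = Iw[i, 2, 0] * om[i, 0] + Iw[i, 2, 1] * om[i, 1] + Iw[i, 2, 2] * om[i, 2]
        N0 = (Iw[i, 0, 0] * al[i, 0] + Iw[i, 0, 1] * al[i, 1] + Iw[i, 0, 2] * al[i, 2]
              + om[i, 1] * Iw2 - om[i, 2] * Iw1)
        N1 = (Iw[i, 1, 0] * al[i, 0] + Iw[i, 1, 1] * al[i, 1] + Iw[i, 1, 2] * al[i, 2]
              + om[i, 2] * Iw0 - om[i, 0] * Iw2)
        N2 = (Iw[i, 2, 0] * al[i, 0] + Iw[i, 2, 1] * al[i, 1] + Iw[i, 2, 2] * al[i, 2]
              + om[i, 0] * Iw1 - om[i, 1] * Iw0)

        f0 = F0 + fn0
        f1 = F1 + fn1
        f2 = F2 + fn2
        # moment about this joint origin
        d0 = cw[i, 0] - o[i, 0]
        d1 = cw[i, 1] - o[i, 1]
        d2 = cw[i, 2] - o[i, 2]
        n0 = N0 + nn0 + d1 * F2 - d2 * F1
        n1 = N1 + nn1 + d2 * F0 - d0 * F2
        n2 = N2 + nn2 + d0 * F1 - d1 * F0
        if i < 2:
            e0 = on0 - o[i, 0]
            e1 = on1 - o[i, 1]
            e2 = on2 - o[i, 2]
            n0 += e1 * fn2 - e2 * fn1
            n1 += e2 * fn0 - e0 * fn2
            n2 += e0 * fn1 - e1 * fn0
        else:
            # external force applied ON the link at the end-effector point
            p0 = Rw[i, 0, 0] * ee[0] + Rw[i, 0, 1] * ee[1] + Rw[i, 0, 2] * ee[2]
            p1 = Rw[i, 1, 0] * ee[0] + Rw[i, 1, 1] * ee[1] + Rw[i, 1, 2] * ee[2]
            p2 = Rw[i, 2, 0] * ee[0] + Rw[i, 2, 1] * ee[1] + Rw[i, 2, 2] * ee[2]
            f0 -= fext[0]
            f1 -= fext[1]
            f2 -= fext[2]
            n0 -= p1 * fext[2] - p2 * fext[1]
            n1 -= p2 * fext[0] - p0 * fext[2]
            n2 -= p0 * fext[1] - p1 * fext[0]
        tau[i] = aw[i, 0] * n0 + aw[i, 1] * n1 + aw[i, 2] * n2
        fn0, fn1, fn2 = f0, f1, f2
        nn0, nn1, nn2 = n0, n1, n2
        on0, on1, on2 = o[i, 0], o[i, 1], o[i, 2]
    return tau


@njit(cache=True)
def mass_matrix(q, axes, offs, coms, masses, inert):
    """Joint-space inertia matrix via the composite-rigid-body recursion."""
    Rw = np.empty((3, 3, 3))
    aw = np.empty((3, 3))
    om = np.empty((3, 3))
    al = np.empty((3, 3))
    o = np.empty((3, 3))
    ao = np.empty((3, 3))
    cw = np.empty((3, 3))
    ac = np.empty((3, 3))
    Iw = np.empty((3, 3, 3))
    z3 = np.zeros(3)
    g0 = np.zeros(3)
    _outward_kinematics(q, z3, z3, axes, offs, coms, inert, g0,
                        Rw, aw, om, al, o, ao, cw, ac, Iw)

    M = np.empty((3, 3))
    # composite body j..2, accumulated from the tip inwards
    mc = 0.0
    S0 = S1 = S2 = 0.0         # first moment of mass about the world origin
    Io = np.zeros((3, 3))      # composite inertia about the world origin
    for j in range(2, -1, -1):
        m = masses[j]
        mc += m
        cx, cy, cz = cw[j, 0], cw[j, 1], cw[j, 2]
        S0 += m * cx
        S1 += m * cy
        S2 += m * cz
        # shift link inertia from its COM to the world origin
        c2 = cx * cx + cy * cy + cz * cz
        Io[0, 0] += Iw[j, 0, 0] + m * (c2 - cx * cx)
        Io[0, 1] += Iw[j, 0, 1] - m * cx * cy
        Io[0, 2] += Iw[j, 0, 2] - m * cx * cz
        Io[1, 1] += Iw[j, 1, 1] + m * (c2 - cy * cy)
        Io[1, 2] += Iw[j, 1, 2] - m * cy * cz
        Io[2, 2] += Iw[j, 2, 2] + m * (c2 - cz * cz)

        cc0, cc1, cc2 = S0 / mc, S1 / mc, S2 / mc
        # composite inertia about its own COM
        q2 = cc0 * cc0 + cc1 * cc1 + cc2 * cc2
        I00 = Io[0, 0] - mc * (q2 - cc0 * cc0)
        I01 = Io[0, 1] + mc * cc0 * cc1
        I02 = Io[0, 2] + mc * cc0 * cc2
        I11 = Io[1, 1] - mc * (q2 - cc1 * cc1)
        I12 = Io[1, 2] + mc * cc1 * cc2
        I22 = Io[2, 2] - mc * (q2 - cc2 * cc2)

        a0, a1, a2 = aw[j, 0], aw[j, 1], aw[j, 2]
        # unit qdd_j: composite angular acc = a, COM linear acc = a x (cc - o_j)
        r0 = cc0 - o[j, 0]
        r1 = cc1 - o[j, 1]
        r2 = cc2 - o[j, 2]
        F0 = mc * (a1 * r2 - a2 * r1)
        F1 = mc * (a2 * r0 - a0 * r2)
        F2 = mc * (a0 * r1 - a1 * r0)
        Ia0 = I00 * a0 + I01 * a1 + I02 * a2
        Ia1 = I01 * a0 + I11 * a1 + I12 * a2
        Ia2 = I02 * a0 + I12 * a1 + I22 * a2
        for i in range(j + 1):
            d0 = cc0 - o[i, 0]
            d1 = cc1 - o[i, 1]
            d2 = cc2 - o[i, 2]
            n0 = Ia0 + d1 * F2 - d2 * F1
            n1 = Ia1 + d2 * F0 - d0 * F2
            n2 = Ia2 + d0 * F1 - d1 * F0
            Mij = aw[i, 0] * n0 + aw[i, 1] * n1 + aw[i, 2] * n2
            M[i, j] = Mij
            M[j, i] = Mij
    return M


@njit(cache=True)
def _solve33(M, b, out):
    """Cramer solve for a well-conditioned 3x3 system."""
    a, bb, c = M[0, 0], M[0, 1], M[0, 2]
    d, e, f = M[1, 0], M[1, 1], M[1, 2]
    g, h, i = M[2, 0], M[2, 1], M[2, 2]
    A = e * i - f * h
    B = c * h - bb * i
    C = bb * f - c * e
    det = a * A + d * B + g * C
    D = f * g - d * i
    E = a * i - c * g
    F = c * d - a * f
    G = d * h - e * g
    H = bb * g - a * h
    I = a * e - bb * d
    out[0] = (A * b[0] + B * b[1] + C * b[2]) / det
    out[1] = (D * b[0] + E * b[1] + F * b[2]) / det
    out[2] = (G * b[0] + H * b[1] + I * b[2]) / det


@njit(cache=True)
def forward_dynamics(q, qd, tau, axes, offs, coms, masses, inert, grav, ee, fext, visc):
    """Solve M(q) qdd = tau - bias(q, qd, fext) - visc*qd."""
    z3 = np.zeros(3)
    bias = rne(q, qd, z3, axes, offs, coms, masses, inert, grav, ee, fext)
    M = mass_matrix(q, axes, offs, coms, masses, inert)
    rhs = np.empty(3)
    for j in range(3):
        rhs[j] = tau[j] - bias[j] - visc[j] * qd[j]
    qdd = np.empty(3)
    _solve33(M, rhs, qdd)
    return qdd


@njit(cache=True)
def _field_at(t, ff_on, ff_amp, ff_omega, ff_phase, f):
    for k in range(3):
        f[k] = ff_amp[k] * np.cos(ff_omega * t + ff_phase[k]) if ff_on else 0.0


@njit(cache=True)
def rk4_step(q, qd, tau, t, dt, axes, offs, coms, masses, inert, grav, ee,
             visc, ff_on, ff_amp, ff_omega, ff_phase):
    """One fixed-step RK4 integration of the plant under constant torque.

    The external force field is evaluated at the sub-step times; the torque
    is held constant over the step (zero-order hold of the controller).
    """
    f = np.empty(3)
    _field_at(t, ff_on, ff_amp, ff_omega, ff_phase, f)
    k1v = forward_dynamics(q, qd, tau, axes, offs, coms, masses, inert, grav, ee, f, visc)

    _field_at(t + 0.5 * dt, ff_on, ff_amp, ff_omega, ff_phase, f)
    q2 = q + 0.5 * dt * qd
    v2 = qd + 0.5 * dt * k1v
    k2v = forward_dynamics(q2, v2, tau, axes, offs, coms, masses, inert, grav, ee, f, visc)

    q3 = q + 0.5 * dt * v2
    v3 = qd + 0.5 * dt * k2v
    k3v = forward_dynamics(q3, v3, tau, axes, offs, coms, masses, inert, grav, ee, f, visc)

    _field_at(t + dt, ff_on, ff_amp, ff_omega, ff_phase, f)
    q4 = q + dt * v3
    v4 = qd + dt * k3v
    k4v = forward_dynamics(q4, v4, tau, axes, offs, coms, masses, inert, grav, ee, f, visc)

    q_new = q + (dt / 6.0) * (qd + 2.0 * v2 + 2.0 * v3 + v4)
    qd_new = qd + (dt / 6.0) * (k1v + 2.0 * k2v + 2.0 * k3v + k4v)
    return q_new, qd_new


@njit(cache=True)
def _decay(x, alpha):
    return np.exp(-alpha * np.log1p(x))


@njit(cache=True)
def _pow_unit(x, alpha):
    if x <= 0.0:
        return 0.0
    return np.exp(alpha * np.log(x))


@njit(cache=True)
def trial_kernel(
    # plant (payload folded in)
    axes, offs, coms, masses, inert, grav, ee, visc,
    # force field
    ff_on, ff_amp, ff_omega, ff_phase,
    # feedforward command and desired positions (n_steps,3) / (n_steps+1,3)
    tau_crude, q_des,
    # network weights (mutated in place)
    w_pf, w_mf, w_pc, w_io,
    # scalars
    mf_baseline, dcn_cap, gain, e_sat, dt,
    torque_limit,
    # plasticity constants
    pf_ltp, pf_ltd, mf_ltp, mf_ltd, pcd_ltp, pcd_ltd, mtp, mtd, alpha, w_max,
    en_pf, en_mf, en_pcd, en_io, pcd_linear,
    # IO signal timing, in control steps: the error measured at the end of
    # step k reaches the olive (and hence the DCN drive and every learning
    # rule) at step k + 1 + sensor_delay; on arrival the PF-PC rule credits
    # the granular state active teach_offset steps before the arrival step.
    sensor_delay, teach_offset,
    # IO arrival pipeline, shape (sensor_delay + 1, 6), zero-initialized
    io_buf,
    # initial plant state
    q0, qd0,
    # instability bounds
    qd_bound, qerr_bound, abort_on_instability,
    # per-step logs (n_steps, ...) filled in place
    log_q, log_qd, log_tau, log_err, log_io,
):
    """Fused closed-loop trial: 1 call = n_steps control steps.

    Returns (abs_err_sum per joint, contrib_io, contrib_ctx, w_io_step_sum
    per muscle, n_steps_done, unstable_flag).
    """
    n_steps = tau_crude.shape[0]
    nj = 3
    nm = 6
    buf_len = io_buf.shape[0]
    buf_head = 0

    q = q0.copy()
    qd = qd0.copy()
    abs_err = np.zeros(nj)
    contrib_io = 0.0
    contrib_ctx = 0.0
    w_io_sum = np.zeros(nm)
    unstable = False
    steps_done = 0

    pc = np.empty(nm)
    dcn = np.empty(nm)
    io = np.empty(nm)
    tau = np.empty(nj)
    err = np.empty(nj)

    for k in range(n_steps):
        t = k * dt
        # IO signal arriving now: error from step k - 1 - sensor_delay
        for i in range(nm):
            io[i] = io_buf[buf_head, i]

        # network
        for i in range(nm):
            w = w_pf[k, i]
            pc[i] = min(max(w, 0.0), 1.0)
            d = mf_baseline * w_mf[i] - pc[i] * w_pc[i] + io[i] * w_io[i]
            if d < 0.0:
                d = 0.0
            if dcn_cap > 0.0 and d > dcn_cap:
                d = dcn_cap
            dcn[i] = d
            contrib_io += io[i] * w_io[i]
            ctx = mf_baseline * w_mf[i] - pc[i] * w_pc[i]
            contrib_ctx += abs(ctx)
            w_io_sum[i] += w_io[i]

        # torque command: crude feedforward + cerebellar correction, saturated
        for j in range(nj):
            tc = tau_crude[k, j] + gain * (dcn[2 * j] - dcn[2 * j + 1])
            lim = torque_limit[j]
            if tc > lim:
                tc = lim
            elif tc < -lim:
                tc = -lim
            tau[j] = tc

        # plant step
        q, qd = rk4_step(q, qd, tau, t, dt, axes, offs, coms, masses, inert,
                         grav, ee, visc, ff_on, ff_amp, ff_omega, ff_phase)

        # error against the desired position at the end of the step
        finite = True
        for j in range(nj):
            if not (np.isfinite(q[j]) and np.isfinite(qd[j])):
                finite = False
        for j in range(nj):
            e = q_des[k + 1, j] - q[j] if finite else qerr_bound
            err[j] = e
            abs_err[j] += abs(e)
            if abs(e) > qerr_bound or abs(qd[j]) > qd_bound:
                unstable = True

        # per-step logs
        for j in range(nj):
            log_q[k, j] = q[j]
            log_qd[k, j] = qd[j]
            log_tau[k, j] = tau[j]
            log_err[k, j] = err[j]
        for i in range(nm):
            log_io[k, i] = io[i]

        # plasticity driven by the IO signal arriving this step. The PF-PC
        # rule credits the granular state whose motor action the arriving
        # error reflects (teach_offset steps back: loop step + sensor
        # latency + eligibility lag); the DCN gain rules act on the current
        # step's rates.
        kc = k - teach_offset
        for i in range(nm):
            if en_pf and kc >= 0:
                w = w_pf[kc, i] + pf_ltp * _decay(io[i], alpha) - pf_ltd * io[i]
                w_pf[kc, i] = min(max(w, 0.0), w_max)
            if en_mf:
                w = w_mf[i] + mf_ltp * _decay(pc[i], alpha) - mf_ltd * pc[i]
                w_mf[i] = min(max(w, 0.0), w_max)
            if en_pcd:
                gate = pc[i] * alpha if pcd_linear else _pow_unit(pc[i], alpha)
                w = (w_pc[i] + pcd_ltp * gate * (1.0 - _decay(dcn[i], alpha))
                     - pcd_ltd * (1.0 - pc[i]))
                w_pc[i] = min(max(w, 0.0), w_max)
            if en_io:
                w = w_io[i] + mtp * io[i] - mtd * _decay(io[i], alpha)
                w_io[i] = min(max(w, 0.0), w_max)

        # push the freshly measured error into the arrival pipeline: with a
        # buffer of length sensor_delay + 1 and the head advancing once per
        # step, it re-surfaces at step k + 1 + sensor_delay
        for j in range(nj):
            ag = err[j] / e_sat
            io_buf[buf_head, 2 * j] = min(max(ag, 0.0), 1.0)
            io_buf[buf_head, 2 * j + 1] = min(max(-ag, 0.0), 1.0)
        buf_head = (buf_head + 1) % buf_len

        steps_done = k + 1
        if unstable and abort_on_instability:
            break
        if not finite:
            break

    return abs_err, contrib_io, contrib_ctx, w_io_sum, steps_done, unstable
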