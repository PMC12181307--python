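"""Numba-compiled inner loop of the planar musculoskeletal simulator.

All functions here operate on flat numpy arrays unpacked from a compiled
model (see :mod:`morphocurl.dynamics`).  The formulation is generalized
coordinates q = [base_x, base_y, base_angle, joint angles...] over a
kinematic tree of planar rigid bodies:

* mass matrix  M(q) = sum_i  m_i Jv_i^T Jv_i + I_i Jw_i^T Jw_i,
* bias forces from the q_ddot = 0 (centripetal) accelerations of each COM,
* muscles as straight-line path actuators: tension F maps to generalized
  force -F dL/dq,
* Hunt-Crossley point contact with a regularized Coulomb + viscous friction
  cone against the ground plane y = 0,
* soft joint-range stops and light viscous joint damping,
* semi-implicit Euler integration on the unconstrained (free) coordinates.

Scalar Hill-curve helpers mirror :mod:`morphocurl.musculotendon`; agreement
between the two is covered by tests.
"""

import numpy as np
from numba import njit

VMAX_NORM = 10.0  # maximal shortening velocity in optimal fiber lengths/s
FRICTION_VREG = 0.01  # m/s, tanh regularization of Coulomb friction


@njit(cache=True)
def _fl(lnorm):
    d = (lnorm - 1.0) / 0.45
    return np.exp(-d * d)


@njit(cache=True)
def _fv(vnorm):
    v = vnorm
    if v < -1.0:
        v = -1.0
    elif v > 1.0:
        v = 1.0
    if v < 0.0:
        out = (1.0 + v) / (1.0 - v / 0.25)
    else:
        # eccentric branch slope-matched to concentric at v = 0 (slope 5)
        out = 1.5 - 0.5 / (1.0 + 10.0 * v)
    if out < 0.0:
        out = 0.0
    return out


@njit(cache=True)
def _fp(lnorm):
    s = lnorm - 1.0
    if s <= 0.0:
        return 0.0
    return (np.exp(4.0 * s / 0.6) - 1.0) / (np.exp(4.0) - 1.0)


@njit(cache=True)
def _fk(q, v, parent, jtype, dof_of_body, anchor, com_l,
        org, ang, w, vorg, com, vcom):
    """Forward kinematics + velocities; bodies are parent-before-child."""
    nb = parent.shape[0]
    for i in range(nb):
        if parent[i] < 0:  # floating base
            org[i, 0] = q[0]
            org[i, 1] = q[1]
            ang[i] = q[2]
            w[i] = v[2]
            vorg[i, 0] = v[0]
            vorg[i, 1] = v[1]
        else:
            p = parent[i]
            ca = np.cos(ang[p])
            sa = np.sin(ang[p])
            rx = ca * anchor[i, 0] - sa * anchor[i, 1]
            ry = sa * anchor[i, 0] + ca * anchor[i, 1]
            org[i, 0] = org[p, 0] + rx
            org[i, 1] = org[p, 1] + ry
            vorg[i, 0] = vorg[p, 0] - w[p] * ry
            vorg[i, 1] = vorg[p, 1] + w[p] * rx
            if jtype[i] == 1:  # revolute
                ang[i] = ang[p] + q[dof_of_body[i]]
                w[i] = w[p] + v[dof_of_body[i]]
            else:  # fixed
                ang[i] = ang[p]
                w[i] = w[p]
        ca = np.cos(ang[i])
        sa = np.sin(ang[i])
        cx = ca * com_l[i, 0] - sa * com_l[i, 1]
        cy = sa * com_l[i, 0] + ca * com_l[i, 1]
        com[i, 0] = org[i, 0] + cx
        com[i, 1] = org[i, 1] + cy
        vcom[i, 0] = vorg[i, 0] - w[i] * cy
        vcom[i, 1] = vorg[i, 1] + w[i] * cx


@njit(cache=True)
def _substep(q, v, act, dt, g,
             parent, jtype, dof_of_body, anchor, com_l, mass, inertia,
             affects, dof_body, aptr, adofs, free,
             qmin, qmax, klim, dlim, djnt, dof_is_rev,
             mptr, mbody, mpt, lopt, lslack, fmax, menabled,
             cbody, cpt, cfoot, ck, ccd, cmus, cmud, cmuv, cvreg, cexp,
             fext, fext_body,
             org, ang, w, vorg, com, vcom,
             Jo, M, Q, dLdq, Mf, Qf,
             out_mlen, out_mvel, out_mforce, out_grf):
    nb = parent.shape[0]
    n = q.shape[0]
    nm = mptr.shape[0] - 1
    nc = cbody.shape[0]

    _fk(q, v, parent, jtype, dof_of_body, anchor, com_l, org, ang, w, vorg, com, vcom)

    for a in range(n):
        Q[a] = 0.0
        for b in range(n):
            M[a, b] = 0.0

    # translational Jacobian of every body-frame origin, active dofs only;
    # a point p on body i then has column d:
    #   Jo[i,:,d] + affects[i,d] * zcross(p - org_i)
    for i in range(nb):
        for k in range(aptr[i], aptr[i + 1]):
            d = adofs[k]
            if d == 0:
                Jo[i, 0, d] = 1.0
                Jo[i, 1, d] = 0.0
            elif d == 1:
                Jo[i, 0, d] = 0.0
                Jo[i, 1, d] = 1.0
            else:
                if d == 2:
                    ax = q[0]
                    ay = q[1]
                else:
                    b = dof_body[d]
                    ax = org[b, 0]
                    ay = org[b, 1]
                Jo[i, 0, d] = -(org[i, 1] - ay)
                Jo[i, 1, d] = org[i, 0] - ax

    # inertia, bias (centripetal) and gravity, body by body
    for i in range(nb):
        # bias acceleration of COM with q_ddot = 0:
        # accumulate -w^2 r along the chain from the base
        abx = 0.0
        aby = 0.0
        j = i
        while parent[j] >= 0:
            p = parent[j]
            abx -= w[p] * w[p] * (org[j, 0] - org[p, 0])
            aby -= w[p] * w[p] * (org[j, 1] - org[p, 1])
            j = p
        rcx = com[i, 0] - org[i, 0]
        rcy = com[i, 1] - org[i, 1]
        abx -= w[i] * w[i] * rcx
        aby -= w[i] * w[i] * rcy

        for ka in range(aptr[i], aptr[i + 1]):
            a = adofs[ka]
            rot_a = 1.0 if a >= 2 else 0.0
            jax = Jo[i, 0, a] - rot_a * rcy
            jay = Jo[i, 1, a] + rot_a * rcx
            # gravity and bias
            Q[a] += mass[i] * (-g * jay) - mass[i] * (jax * abx + jay * aby)
            for kb in range(ka, aptr[i + 1]):
                b = adofs[kb]
                rot_b = 1.0 if b >= 2 else 0.0
                jbx = Jo[i, 0, b] - rot_b * rcy
                jby = Jo[i, 1, b] + rot_b * rcx
                M[a, b] += mass[i] * (jax * jbx + jay * jby) + inertia[i] * rot_a * rot_b

    for a in range(n):
        for b in range(a + 1, n):
            M[b, a] = M[a, b]

    # joint stops and damping
    for d in range(3, n):
        if dof_is_rev[d] == 0:
            continue
        t = -djnt[d] * v[d]
        if q[d] > qmax[d]:
            t += -klim[d] * (q[d] - qmax[d]) - dlim[d] * v[d]
        elif q[d] < qmin[d]:
            t += -klim[d] * (q[d] - qmin[d]) - dlim[d] * v[d]
        Q[d] += t

    # muscles: path length, velocity, tension, generalized force -F dL/dq
    for mi in range(nm):
        L = 0.0
        Ldot = 0.0
        for a in range(n):
            dLdq[a] = 0.0
        for k in range(mptr[mi], mptr[mi + 1] - 1):
            b1 = mbody[k]
            b2 = mbody[k + 1]
            c1 = np.cos(ang[b1]); s1 = np.sin(ang[b1])
            c2 = np.cos(ang[b2]); s2 = np.sin(ang[b2])
            p1x = org[b1, 0] + c1 * mpt[k, 0] - s1 * mpt[k, 1]
            p1y = org[b1, 1] + s1 * mpt[k, 0] + c1 * mpt[k, 1]
            p2x = org[b2, 0] + c2 * mpt[k + 1, 0] - s2 * mpt[k + 1, 1]
            p2y = org[b2, 1] + s2 * mpt[k + 1, 0] + c2 * mpt[k + 1, 1]
            dx = p2x - p1x
            dy = p2y - p1y
            seg = np.sqrt(dx * dx + dy * dy)
            if seg < 1e-12:
                continue
            ux = dx / seg
            uy = dy / seg
            L += seg
            v1x = vorg[b1, 0] - w[b1] * (p1y - org[b1, 1])
            v1y = vorg[b1, 1] + w[b1] * (p1x - org[b1, 0])
            v2x = vorg[b2, 0] - w[b2] * (p2y - org[b2, 1])
            v2y = vorg[b2, 1] + w[b2] * (p2x - org[b2, 0])
            Ldot += ux * (v2x - v1x) + uy * (v2y - v1y)
            r2x = p2x - org[b2, 0]
            r2y = p2y - org[b2, 1]
            for ka in range(aptr[b2], aptr[b2 + 1]):
                a = adofs[ka]
                rot = 1.0 if a >= 2 else 0.0
                dLdq[a] += ux * (Jo[b2, 0, a] - rot * r2y) + uy * (Jo[b2, 1, a] + rot * r2x)
            r1x = p1x - org[b1, 0]
            r1y = p1y - org[b1, 1]
            for ka in range(aptr[b1], aptr[b1 + 1]):
                a = adofs[ka]
                rot = 1.0 if a >= 2 else 0.0
                dLdq[a] -= ux * (Jo[b1, 0, a] - rot * r1y) + uy * (Jo[b1, 1, a] + rot * r1x)
        out_mlen[mi] = L
        out_mvel[mi] = Ldot
        if menabled[mi] == 0:
            out_mforce[mi] = 0.0
            continue
        lnorm = (L - lslack[mi]) / lopt[mi]
        vnorm = Ldot / (lopt[mi] * VMAX_NORM)
        F = fmax[mi] * (act[mi] * _fl(lnorm) * _fv(vnorm) + _fp(lnorm))
        if F < 0.0:
            F = 0.0
        out_mforce[mi] = F
        for a in range(n):
            Q[a] -= F * dLdq[a]

    # ground contact (plane y = 0)
    out_grf[0] = 0.0
    out_grf[1] = 0.0
    for ci in range(nc):
        b = cbody[ci]
        ca = np.cos(ang[b]); sa = np.sin(ang[b])
        px = org[b, 0] + ca * cpt[ci, 0] - sa * cpt[ci, 1]
        py = org[b, 1] + sa * cpt[ci, 0] + ca * cpt[ci, 1]
        pen = -py
        if pen <= 0.0:
            continue
        vx = vorg[b, 0] - w[b] * (py - org[b, 1])
        vy = vorg[b, 1] + w[b] * (px - org[b, 0])
        pend = -vy
        N = ck[ci] * pen ** cexp[ci] * (1.0 + ccd[ci] * pend)
        if N < 0.0:
            N = 0.0
        Ft = -N * cmud[ci] * np.tanh(vx / cvreg[ci]) - N * cmuv[ci] * vx
        cap = cmus[ci] * N + cmuv[ci] * abs(vx) * N
        if Ft > cap:
            Ft = cap
        elif Ft < -cap:
            Ft = -cap
        out_grf[cfoot[ci]] += N
        rx = px - org[b, 0]
        ry = py - org[b, 1]
        for ka in range(aptr[b], aptr[b + 1]):
            a = adofs[ka]
            rot = 1.0 if a >= 2 else 0.0
            Q[a] += (Jo[b, 0, a] - rot * ry) * Ft + (Jo[b, 1, a] + rot * rx) * N

    # external perturbation at a body COM
    if fext_body >= 0 and (fext[0] != 0.0 or fext[1] != 0.0):
        i = fext_body
        rx = com[i, 0] - org[i, 0]
        ry = com[i, 1] - org[i, 1]
        for ka in range(aptr[i], aptr[i + 1]):
            a = adofs[ka]
            rot = 1.0 if a >= 2 else 0.0
            Q[a] += (Jo[i, 0, a] - rot * ry) * fext[0] + (Jo[i, 1, a] + rot * rx) * fext[1]

    # reduce to free coordinates and integrate (Mf/Qf sized by caller)
    ia = 0
    for a in range(n):
        if not free[a]:
            continue
        Qf[ia] = Q[a]
        ib = 0
        for b in range(n):
            if not free[b]:
                continue
            Mf[ia, ib] = M[a, b]
            ib += 1
        ia += 1
    acc = np.linalg.solve(Mf, Qf)
    ia = 0
    for d in range(n):
        if free[d]:
            v[d] += dt * acc[ia]
            ia += 1
        q[d] += dt * v[d]


@njit(cache=True)
def control_step(q, v, act, u, dt_ctrl, nsub, g,
                 parent, jtype, dof_of_body, anchor, com_l, mass, inertia,
                 affects, dof_body, aptr, adofs, free,
                 qmin, qmax, klim, dlim, djnt, dof_is_rev,
                 mptr, mbody, mpt, lopt, lslack, fmax, menabled,
                 tau_act, tau_deact,
                 cbody, cpt, cfoot, ck, ccd, cmus, cmud, cmuv, cvreg, cexp,
                 fext, fext_body,
                 out_mlen, out_mvel, out_mforce, out_grf,
                 out_com, out_vcom, out_ang, out_w):
    """One control period: activation low-pass then nsub physics substeps."""
    nm = act.shape[0]
    for mi in range(nm):
        ui = u[mi]
        if ui < 0.0:
            ui = 0.0
        elif ui > 1.0:
            ui = 1.0
        if menabled[mi] == 0:
            ui = 0.0
        tau = tau_act[mi] if ui > act[mi] else tau_deact[mi]
        a = ui + (act[mi] - ui) * np.exp(-dt_ctrl / tau)
        if a < 0.0:
            a = 0.0
        elif a > 1.0:
            a = 1.0
        act[mi] = a

    nb = parent.shape[0]
    n = q.shape[0]
    org = np.empty((nb, 2))
    ang = np.empty(nb)
    w = np.empty(nb)
    vorg = np.empty((nb, 2))
    com = np.empty((nb, 2))
    vcom = np.empty((nb, 2))
    Jo = np.zeros((nb, 2, n))
    M = np.empty((n, n))
    Q = np.empty(n)
    dLdq = np.empty(n)
    nf = 0
    for d in range(n):
        if free[d]:
            nf += 1
    Mf = np.empty((nf, nf))
    Qf = np.empty(nf)
    dt = dt_ctrl / nsub
    for _ in range(nsub):
        _substep(q, v, act, dt, g,
                 parent, jtype, dof_of_body, anchor, com_l, mass, inertia,
                 affects, dof_body, aptr, adofs, free,
                 qmin, qmax, klim, dlim, djnt, dof_is_rev,
                 mptr, mbody, mpt, lopt, lslack, fmax, menabled,
                 cbody, cpt, cfoot, ck, ccd, cmus, cmud, cmuv, cvreg, cexp,
                 fext, fext_body,
                 org, ang, w, vorg, com, vcom,
                 Jo, M, Q, dLdq, Mf, Qf,
                 out_mlen, out_mvel, out_mforce, out_grf)
    for i in range(nb):
        out_com[i, 0] = com[i, 0]
        out_com[i, 1] = com[i, 1]
        out_vcom[i, 0] = vcom[i, 0]
        out_vcom[i, 1] = vcom[i, 1]
        out_ang[i] = ang[i]
        out_w[i] = w[i]
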