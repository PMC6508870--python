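"""Numerical core: Newton-Euler dynamics of the bushing chain, compiled with numba.

The chain is a set of rigid bodies coupled only through force elements
(6-DoF Kelvin-Voigt bushings), so the equations of motion decouple per body
and no constrained multibody solve is needed.  Constrained coordinates are
handled by masking their derivatives.  Rotations are parameterised as
body-fixed X-Y-Z Euler angle deviations from each body's rest orientation;
the gyroscopic term and the Euler-rate/angular-velocity distinction are
neglected, which is accurate for the sub-degree rotations reached in the
few-millisecond impact windows simulated here.

State layout: ``Q``/``U`` of length ``6 * n_bodies``; per body
``(tx, ty, tz, rx, ry, rz)`` — translations in metres along the global
axes, rotations in radians.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# status codes returned by the integrator
OK = 0
DIVERGED = 1

# divergence guards: the specimen is ~0.2 m tall and rotations must stay
# far from gimbal lock for the Euler parameterisation to make sense
_MAX_TRANSLATION = 1.0   # m
_MAX_ROTATION = 1.0      # rad


@njit(cache=False)
def _rot_xyz(ax, ay, az, R):
    cx, sx = np.cos(ax), np.sin(ax)
    cy, sy = np.cos(ay), np.sin(ay)
    cz, sz = np.cos(az), np.sin(az)
    R[0, 0] = cy * cz
    R[0, 1] = -cy * sz
    R[0, 2] = sy
    R[1, 0] = cx * sz + sx * sy * cz
    R[1, 1] = cx * cz - sx * sy * sz
    R[1, 2] = -sx * cy
    R[2, 0] = sx * sz - cx * sy * cz
    R[2, 1] = sx * cz + cx * sy * sz
    R[2, 2] = cx * cy


@njit(cache=False)
def _euler_xyz(R, out):
    sy = R[0, 2]
    if sy > 1.0:
        sy = 1.0
    elif sy < -1.0:
        sy = -1.0
    out[0] = np.arctan2(-R[1, 2], R[2, 2])
    out[1] = np.arcsin(sy)
    out[2] = np.arctan2(-R[0, 1], R[0, 0])


@njit(cache=False)
def _rhs(Q, U, fext,
         p0, R0, mass, mextra, Iinv, free_mask, grav, const_F, ext_body,
         jca, jcr, joc, jRjc, jacr, jRjcr, jk, jb,
         Qd, Ud):
    """Time derivative of (Q, U); ``fext`` is the compressive drive force (N)."""
    nb = mass.shape[0]
    nj = jca.shape[0]

    # body poses and velocities
    P = np.empty((nb, 3))
    R = np.empty((nb, 3, 3))
    V = np.empty((nb, 3))
    W = np.empty((nb, 3))        # world angular velocity (small-angle)
    F = np.empty((nb, 3))
    T = np.zeros((nb, 3))
    Rl = np.empty((3, 3))
    for b in range(nb):
        o = 6 * b
        _rot_xyz(Q[o + 3], Q[o + 4], Q[o + 5], Rl)
        for i in range(3):
            P[b, i] = p0[b, i] + Q[o + i]
            V[b, i] = U[o + i]
            wi = 0.0
            ri0 = 0.0
            ri1 = 0.0
            ri2 = 0.0
            for k in range(3):
                wi += R0[b, i, k] * U[o + 3 + k]
                ri0 += R0[b, i, k] * Rl[k, 0]
                ri1 += R0[b, i, k] * Rl[k, 1]
                ri2 += R0[b, i, k] * Rl[k, 2]
            W[b, i] = wi
            R[b, i, 0] = ri0
            R[b, i, 1] = ri1
            R[b, i, 2] = ri2
        # gravity + constant preload forces
        for i in range(3):
            F[b, i] = mass[b] * grav[i] + const_F[b, i]
    # external compressive drive along -y at one body's COM
    F[ext_body, 1] -= fext

    d = np.empty(3)
    dd = np.empty(3)
    th = np.empty(3)
    om = np.empty(3)
    fj = np.empty(3)
    mj = np.empty(3)
    Fw = np.empty(3)
    Mw = np.empty(3)
    rca = np.empty(3)
    rcr = np.empty(3)
    RJ = np.empty((3, 3))
    Rrel = np.empty((3, 3))
    tmp = np.empty((3, 3))
    for j in range(nj):
        ca = jca[j]
        cr = jcr[j]
        # joint frame carried by the caudal body
        for i in range(3):
            for k in range(3):
                s = 0.0
                for m in range(3):
                    s += R[ca, i, m] * jRjc[j, m, k]
                RJ[i, k] = s
            s = 0.0
            for m in range(3):
                s += R[ca, i, m] * joc[j, m]
            rca[i] = s
            s = 0.0
            for m in range(3):
                s += R[cr, i, m] * jacr[j, m]
            rcr[i] = s
        # translational deflection and rate in the joint frame
        for i in range(3):
            gap_i = P[cr, i] + rcr[i] - (P[ca, i] + rca[i])
            d[i] = gap_i
        for i in range(3):
            s = 0.0
            for m in range(3):
                s += RJ[m, i] * d[m]
            dd[i] = s
        for i in range(3):
            d[i] = dd[i]
        # relative velocity of the attachment points
        vrel0 = V[cr, 0] + (W[cr, 1] * rcr[2] - W[cr, 2] * rcr[1]) \
            - (V[ca, 0] + (W[ca, 1] * rca[2] - W[ca, 2] * rca[1]))
        vrel1 = V[cr, 1] + (W[cr, 2] * rcr[0] - W[cr, 0] * rcr[2]) \
            - (V[ca, 1] + (W[ca, 2] * rca[0] - W[ca, 0] * rca[2]))
        vrel2 = V[cr, 2] + (W[cr, 0] * rcr[1] - W[cr, 1] * rcr[0]) \
            - (V[ca, 2] + (W[ca, 0] * rca[1] - W[ca, 1] * rca[0]))
        for i in range(3):
            dd[i] = RJ[0, i] * vrel0 + RJ[1, i] * vrel1 + RJ[2, i] * vrel2
        # rotational deflection: joint frame copy carried by the cranial body
        for i in range(3):
            for k in range(3):
                s = 0.0
                for m in range(3):
                    s += R[cr, i, m] * jRjcr[j, m, k]
                tmp[i, k] = s
        for i in range(3):
            for k in range(3):
                s = 0.0
                for m in range(3):
                    s += RJ[m, i] * tmp[m, k]
                Rrel[i, k] = s
        _euler_xyz(Rrel, th)
        for i in range(3):
            s = 0.0
            for m in range(3):
                s += RJ[m, i] * (W[cr, m] - W[ca, m])
            om[i] = s
        # Kelvin-Voigt wrench on the cranial body, joint frame
        for i in range(3):
            fj[i] = -jk[j, i] * d[i] - jb[j, i] * dd[i]
            mj[i] = -jk[j, 3 + i] * th[i] - jb[j, 3 + i] * om[i]
        for i in range(3):
            s = 0.0
            t = 0.0
            for m in range(3):
                s += RJ[i, m] * fj[m]
                t += RJ[i, m] * mj[m]
            Fw[i] = s
            Mw[i] = t
        # accumulate: force at the attachment point plus pure torque
        F[cr, 0] += Fw[0]
        F[cr, 1] += Fw[1]
        F[cr, 2] += Fw[2]
        T[cr, 0] += rcr[1] * Fw[2] - rcr[2] * Fw[1] + Mw[0]
        T[cr, 1] += rcr[2] * Fw[0] - rcr[0] * Fw[2] + Mw[1]
        T[cr, 2] += rcr[0] * Fw[1] - rcr[1] * Fw[0] + Mw[2]
        F[ca, 0] -= Fw[0]
        F[ca, 1] -= Fw[1]
        F[ca, 2] -= Fw[2]
        T[ca, 0] -= rca[1] * Fw[2] - rca[2] * Fw[1] + Mw[0]
        T[ca, 1] -= rca[2] * Fw[0] - rca[0] * Fw[2] + Mw[1]
        T[ca, 2] -= rca[0] * Fw[1] - rca[1] * Fw[0] + Mw[2]

    # accelerations (per-body diagonal mass matrix)
    for b in range(nb):
        o = 6 * b
        mtot = mass[b] + mextra[b]
        for i in range(3):
            Qd[o + i] = U[o + i] * free_mask[b, i]
            Ud[o + i] = (F[b, i] / mtot) * free_mask[b, i]
        # torque to body frame, apply inverse inertia, back to rest frame
        tb0 = R[b, 0, 0] * T[b, 0] + R[b, 1, 0] * T[b, 1] + R[b, 2, 0] * T[b, 2]
        tb1 = R[b, 0, 1] * T[b, 0] + R[b, 1, 1] * T[b, 1] + R[b, 2, 1] * T[b, 2]
        tb2 = R[b, 0, 2] * T[b, 0] + R[b, 1, 2] * T[b, 1] + R[b, 2, 2] * T[b, 2]
        wd0 = Iinv[b, 0, 0] * tb0 + Iinv[b, 0, 1] * tb1 + Iinv[b, 0, 2] * tb2
        wd1 = Iinv[b, 1, 0] * tb0 + Iinv[b, 1, 1] * tb1 + Iinv[b, 1, 2] * tb2
        wd2 = Iinv[b, 2, 0] * tb0 + Iinv[b, 2, 1] * tb1 + Iinv[b, 2, 2] * tb2
        ww0 = R[b, 0, 0] * wd0 + R[b, 0, 1] * wd1 + R[b, 0, 2] * wd2
        ww1 = R[b, 1, 0] * wd0 + R[b, 1, 1] * wd1 + R[b, 1, 2] * wd2
        ww2 = R[b, 2, 0] * wd0 + R[b, 2, 1] * wd1 + R[b, 2, 2] * wd2
        a0 = R0[b, 0, 0] * ww0 + R0[b, 1, 0] * ww1 + R0[b, 2, 0] * ww2
        a1 = R0[b, 0, 1] * ww0 + R0[b, 1, 1] * ww1 + R0[b, 2, 1] * ww2
        a2 = R0[b, 0, 2] * ww0 + R0[b, 1, 2] * ww1 + R0[b, 2, 2] * ww2
        for i in range(3):
            Qd[o + 3 + i] = U[o + 3 + i] * free_mask[b, 3 + i]
        Ud[o + 3] = a0 * free_mask[b, 3]
        Ud[o + 4] = a1 * free_mask[b, 4]
        Ud[o + 5] = a2 * free_mask[b, 5]


@njit(cache=False)
def integrate(Q0, U0, n_steps, h, f_half,
              p0, R0, mass, mextra, Iinv, free_mask, grav, const_F, ext_body,
              jca, jcr, joc, jRjc, jacr, jRjcr, jk, jb):
    """Fixed-step classical RK4 over ``n_steps`` of size ``h``.

    ``f_half`` holds the drive force sampled on the half-step grid
    (length ``2 * n_steps + 1``).  Returns (status, step_reached, Q_hist,
    U_hist) with histories of shape ``(n_steps + 1, 6 * n_bodies)``.
    """
    n = Q0.shape[0]
    Qh = np.empty((n_steps + 1, n))
    Uh = np.empty((n_steps + 1, n))
    Qh[0] = Q0
    Uh[0] = U0
    Q = Q0.copy()
    U = U0.copy()
    k1q = np.empty(n); k1u = np.empty(n)
    k2q = np.empty(n); k2u = np.empty(n)
    k3q = np.empty(n); k3u = np.empty(n)
    k4q = np.empty(n); k4u = np.empty(n)
    Qt = np.empty(n); Ut = np.empty(n)
    for s in range(n_steps):
        f0 = f_half[2 * s]
        fm = f_half[2 * s + 1]
        f1 = f_half[2 * s + 2]
        _rhs(Q, U, f0, p0, R0, mass, mextra, Iinv, free_mask, grav, const_F,
             ext_body, jca, jcr, joc, jRjc, jacr, jRjcr, jk, jb, k1q, k1u)
        for i in range(n):
            Qt[i] = Q[i] + 0.5 * h * k1q[i]
            Ut[i] = U[i] + 0.5 * h * k1u[i]
        _rhs(Qt, Ut, fm, p0, R0, mass, mextra, Iinv, free_mask, grav, const_F,
             ext_body, jca, jcr, joc, jRjc, jacr, jRjcr, jk, jb, k2q, k2u)
        for i in range(n):
            Qt[i] = Q[i] + 0.5 * h * k2q[i]
            Ut[i] = U[i] + 0.5 * h * k2u[i]
        _rhs(Qt, Ut, fm, p0, R0, mass, mextra, Iinv, free_mask, grav, const_F,
             ext_body, jca, jcr, joc, jRjc, jacr, jRjcr, jk, jb, k3q, k3u)
        for i in range(n):
            Qt[i] = Q[i] + h * k3q[i]
            Ut[i] = U[i] + h * k3u[i]
        _rhs(Qt, Ut, f1, p0, R0, mass, mextra, Iinv, free_mask, grav, const_F,
             ext_body, jca, jcr, joc, jRjc, jacr, jRjcr, jk, jb, k4q, k4u)
        bad = False
        for i in range(n):
            Q[i] += (h / 6.0) * (k1q[i] + 2.0 * k2q[i] + 2.0 * k3q[i] + k4q[i])
            U[i] += (h / 6.0) * (k1u[i] + 2.0 * k2u[i] + 2.0 * k3u[i] + k4u[i])
            if not np.isfinite(Q[i]):
                bad = True
        if bad:
            return DIVERGED, s, Qh, Uh
        # magnitude guard (checks translations and rotations separately)
        for b in range(mass.shape[0]):
            o = 6 * b
            for i in range(3):
                if abs(Q[o + i]) > _MAX_TRANSLATION or abs(Q[o + 3 + i]) > _MAX_ROTATION:
                    bad = True
        if bad:
            return DIVERGED, s, Qh, Uh
        Qh[s + 1] = Q
        Uh[s + 1] = U
    return OK, n_steps, Qh, Uh
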