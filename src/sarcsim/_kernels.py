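"""Numba-compiled inner loops for the chain integrator.

These kernels mirror the reference operations in :mod:`.halfsarcomere`
(`kinetics_step`, `set_available`, `shift_distribution`) and the
shared-tension force balance of :mod:`.network`, fused into one pass per
time step to avoid per-step Python overhead.  The test suite checks the
fused step against the reference operations composed in numpy.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["chain_step", "kinetics_inplace", "shift_inplace"]


@njit(cache=True)
def _overlap(l, b0, b1, b2, b3):
    if l <= b0 or l >= b3:
        return 0.0
    if l < b1:
        return (l - b0) / (b1 - b0)
    if l <= b2:
        return 1.0
    return (b3 - l) / (b3 - b2)


@njit(cache=True)
def _passive(l, xi, sp, off, lam):
    u = (l - off) / lam
    if u >= 0.0:
        if u > 50.0:
            u = 50.0
        return xi * sp * (np.exp(u) - 1.0)
    return xi * sp * u


@njit(cache=True)
def _passive_stiff(l, xi, sp, off, lam):
    u = (l - off) / lam
    if u >= 0.0:
        if u > 50.0:
            u = 50.0
        return xi * sp / lam * np.exp(u)
    return xi * sp / lam


@njit(cache=True)
def kinetics_inplace(a1, a2, d, n_av, dt,
                     attach_w, k3, g1x, g2, exit1, exit2, f0, k_m3):
    """Pool rescale to ``n_av`` plus one explicit kinetics step, in place.

    ``a1``/``a2`` have shape (U, B); ``d`` and ``n_av`` shape (U,).
    """
    U, B = a1.shape
    t1 = np.empty(B)
    t2 = np.empty(B)
    for i in range(U):
        s1 = 0.0
        s2 = 0.0
        for j in range(B):
            s1 += a1[i, j]
            s2 += a2[i, j]
        tot = d[i] + s1 + s2
        if tot > 0.0:
            sc = n_av[i] / tot
            d[i] *= sc
            for j in range(B):
                a1[i, j] *= sc
                a2[i, j] *= sc
        else:
            d[i] = n_av[i]
            for j in range(B):
                a1[i, j] = 0.0
                a2[i, j] = 0.0
        gsum = 0.0
        for j in range(B):
            t1[j] = a1[i, j] * (1.0 - dt * exit1[j]) \
                + f0 * dt * d[i] * attach_w[j] + dt * k_m3 * a2[i, j]
            t2[j] = a2[i, j] * (1.0 - dt * exit2[j]) + dt * k3[j] * a1[i, j]
            gsum += g1x[j] * a1[i, j] + g2[j] * a2[i, j]
        dn = d[i] * (1.0 - f0 * dt) + dt * gsum
        for j in range(B):
            if t1[j] < 0.0:
                dn += t1[j]
                t1[j] = 0.0
            if t2[j] < 0.0:
                dn += t2[j]
                t2[j] = 0.0
            a1[i, j] = t1[j]
            a2[i, j] = t2[j]
        d[i] = dn


@njit(cache=True)
def _shift_row(a, out, s, B):
    """out[j] = interpolated a[j - s]; returns the mass lost off-axis."""
    k = int(np.floor(s))
    f = s - k
    lost = 0.0
    for j in range(B):
        j1 = j - k
        j2 = j1 - 1
        v = 0.0
        if 0 <= j1 < B:
            v += (1.0 - f) * a[j1]
        if 0 <= j2 < B:
            v += f * a[j2]
        out[j] = v
    for j in range(B):
        lost += a[j]
    for j in range(B):
        lost -= out[j]
    return lost


@njit(cache=True)
def shift_inplace(a1, a2, d, deltas, bin_w):
    """Advect each unit's bound profiles by ``deltas[i]`` nm, in place.

    Shifts larger than 45% of the axis are applied in sub-shifts.  Mass
    pushed off the axis is forcibly detached into ``d``.  Returns
    (bound_before, leaked_total).
    """
    U, B = a1.shape
    tmp = np.empty(B)
    half = 0.45 * (B - 1)
    bound_before = 0.0
    leaked = 0.0
    for i in range(U):
        for j in range(B):
            bound_before += a1[i, j] + a2[i, j]
        s_total = deltas[i] / bin_w
        nsub = 1 + int(np.abs(s_total) / half)
        s = s_total / nsub
        for _ in range(nsub):
            lost = _shift_row(a1[i], tmp, s, B)
            for j in range(B):
                a1[i, j] = tmp[j]
            lost += _shift_row(a2[i], tmp, s, B)
            for j in range(B):
                a2[i, j] = tmp[j]
            d[i] += lost
            leaked += lost
    return bound_before, leaked


@njit(cache=True)
def _solve_chain_tension(A, K, l0, xi, L_target, T0,
                         kcb, sp, off, lam):
    """Newton on the common tension T of one chain.

    Unit force F_i(l) = A_i + K_i (l - l0_i) + P_i(l) is strictly
    increasing; the inner loop inverts it per unit, the outer loop drives
    the total length to ``L_target``.  Returns (T, l_new).
    """
    N = l0.shape[0]
    l = l0.copy()
    T = T0
    tol = 1e-12 * L_target
    if tol < 1e-7:
        tol = 1e-7
    for _ in range(120):
        sum_l = 0.0
        sum_inv = 0.0
        for i in range(N):
            li = l[i]
            for _ in range(80):
                r = A[i] + K[i] * (li - l0[i]) \
                    + _passive(li, xi[i], sp, off, lam) - T
                dF = K[i] + _passive_stiff(li, xi[i], sp, off, lam)
                step = r / dF
                li -= step
                if np.abs(step) < 1e-11:
                    break
            l[i] = li
            sum_l += li
            sum_inv += 1.0 / (K[i] + _passive_stiff(li, xi[i], sp, off, lam))
        g = sum_l - L_target
        if np.abs(g) < tol:
            return T, l
        T = T - g / sum_inv
    return T, l


@njit(cache=True)
def chain_step(a1, a2, d, lengths, zeta, xi, L_target, psi, dt,
               x, attach_w, k3, g1x, g2, exit1, exit2, f0, k_m3, x_ps,
               n0, kcb, sp, off, lam, b0, b1, b2, b3, bin_w,
               tension_out):
    """One fused integrator step for uncoupled chains.

    Arrays have myofibril-major layout: ``a1``/``a2`` shape (M, N, B),
    ``d``/``lengths``/``zeta``/``xi`` shape (M, N).  Updates everything
    in place, stores the common tension per myofibril in ``tension_out``
    and returns (bound_before, leaked, edge_occupancy_fraction).
    """
    M, N, B = a1.shape
    n_av = np.empty(N)
    A = np.empty(N)
    K = np.empty(N)
    deltas = np.empty(N)
    bound_tot = 0.0
    leak_tot = 0.0
    edge = 0.0
    for m in range(M):
        for i in range(N):
            n_av[i] = n0 * zeta[m, i] * psi * _overlap(lengths[m, i],
                                                       b0, b1, b2, b3)
        kinetics_inplace(a1[m], a2[m], d[m], n_av, dt,
                         attach_w, k3, g1x, g2, exit1, exit2, f0, k_m3)
        # force intercept and cross-bridge stiffness per unit
        Fmean = 0.0
        for i in range(N):
            sa = 0.0
            sb = 0.0
            nb = 0.0
            for j in range(B):
                sa += a1[m, i, j] * x[j]
                sb += a2[m, i, j] * (x[j] + x_ps)
                nb += a1[m, i, j] + a2[m, i, j]
            A[i] = kcb * (sa + sb)
            K[i] = kcb * nb
            Fmean += A[i] + _passive(lengths[m, i], xi[m, i], sp, off, lam)
        Fmean /= N
        T, l_new = _solve_chain_tension(A, K, lengths[m], xi[m], L_target,
                                        Fmean, kcb, sp, off, lam)
        tension_out[m] = T
        for i in range(N):
            deltas[i] = l_new[i] - lengths[m, i]
            lengths[m, i] = l_new[i]
        bb, lk = shift_inplace(a1[m], a2[m], d[m], deltas, bin_w)
        bound_tot += bb
        leak_tot += lk
        for i in range(N):
            edge += a1[m, i, 0] + a1[m, i, B - 1] \
                + a2[m, i, 0] + a2[m, i, B - 1]
    edge_frac = edge / bound_tot if bound_tot > 0.0 else 0.0
    return bound_tot, leak_tot, edge_frac
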