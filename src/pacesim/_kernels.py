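"""Numba-compiled time-stepping kernels.

These are internal: the public stepping API lives in :mod:`pacesim.integrators`.
Two model families are compiled separately:

* cardiac family — Aliev-Panfilov-type cells (kind code 0) and passive linear
  tissue (kind code 1), state ``(u, v)``;
* gut family — Corrado-type cells, state ``(u, h)``.

Per-node parameters are packed row-wise into a float64 matrix ``P``:

* cardiac: columns ``k, a, b, eps0, mu1, mu2, ct`` (for passive nodes column 0
  holds ``S`` and column 6 ``ct``);
* gut: columns ``tau_in, tau_out, tau_open, tau_close, u_gate, u_s, b``.

Diffusion/coupling is a sparse matrix in CSR form (``indptr``, ``indices``,
``data``), applied to ``u`` only, with weights in ms^-1.  All kernels detect
upward crossings of a fixed potential level per node (activation times and
cycle counts) and can record traces of selected nodes at a fixed stride.
"""

import numpy as np
from numba import njit

# status codes returned by the stepping kernels
OK = 0
DIVERGED = 1
NO_CONVERGENCE = 2


# ---------------------------------------------------------------------------
# scalar reaction rates
# ---------------------------------------------------------------------------

@njit(cache=True, inline="always")
def _ap_rates(u, v, k, a, b, e0, m1, m2, ct):
    du = ct * (k * u * (u + b) * (1.0 - u) - v * u)
    eps = e0 + m1 * v / (u + m2)
    dv = ct * eps * (-v - k * u * (u - a - 1.0))
    return du, dv


@njit(cache=True, inline="always")
def _ap_jac(u, v, k, a, b, e0, m1, m2, ct):
    duu = ct * (k * ((u + b) * (1.0 - u) + u * (1.0 - u) - u * (u + b)) - v)
    duv = -ct * u
    eps = e0 + m1 * v / (u + m2)
    deps_du = -m1 * v / ((u + m2) * (u + m2))
    deps_dv = m1 / (u + m2)
    g = -v - k * u * (u - a - 1.0)
    dg_du = -k * (2.0 * u - a - 1.0)
    dvu = ct * (deps_du * g + eps * dg_du)
    dvv = ct * (deps_dv * g - eps)
    return duu, duv, dvu, dvv


@njit(cache=True, inline="always")
def _cn_rates(u, h, tin, tout, topen, tclose, ugate, us, b, tsgn):
    # tsgn = +1: convex gate-time blend; -1: as-printed variant
    du = h * u * (u + b) * (1.0 - u) / tin - (1.0 - h) * u / tout
    hi = 0.5 * (1.0 - np.tanh((u - ugate) / us))
    tau = topen * tclose / (topen + tsgn * hi * (tclose - topen))
    dh = (hi - h) / tau
    return du, dh


@njit(cache=True, inline="always")
def _cn_jac(u, h, tin, tout, topen, tclose, ugate, us, b, tsgn):
    duu = h * ((u + b) * (1.0 - u) + u * (1.0 - u) - u * (u + b)) / tin - (1.0 - h) / tout
    duh = u * (u + b) * (1.0 - u) / tin + u / tout
    th = np.tanh((u - ugate) / us)
    hi = 0.5 * (1.0 - th)
    dhi = -0.5 * (1.0 - th * th) / us
    denom = topen + tsgn * hi * (tclose - topen)
    tau = topen * tclose / denom
    dtau = -tsgn * topen * tclose * (tclose - topen) * dhi / (denom * denom)
    dhu = dhi / tau - (hi - h) * dtau / (tau * tau)
    dhh = -1.0 / tau
    return duu, duh, dhu, dhh


# ---------------------------------------------------------------------------
# single-cell integrators
# ---------------------------------------------------------------------------

@njit(cache=True)
def ap_cell_fe(u0, v0, k, a, b, e0, m1, m2, ct, i_ext, dt, n_steps,
               rec_every, out_u, out_v):
    """Forward Euler for one AP-family cell; records every ``rec_every`` steps
    (sample 0 is the initial state).  Returns (u, v, status)."""
    u, v = u0, v0
    j = 0
    if out_u.shape[0] > 0:
        out_u[0] = u
        out_v[0] = v
        j = 1
    for s in range(n_steps):
        du, dv = _ap_rates(u, v, k, a, b, e0, m1, m2, ct)
        u += dt * (du + i_ext)
        v += dt * dv
        if not (np.isfinite(u) and np.isfinite(v)):
            return u, v, DIVERGED
        if (s + 1) % rec_every == 0 and j < out_u.shape[0]:
            out_u[j] = u
            out_v[j] = v
            j += 1
    return u, v, OK


@njit(cache=True)
def ap_cell_be(u0, v0, k, a, b, e0, m1, m2, ct, i_ext, dt, n_steps,
               abs_tol, max_inner, rec_every, out_u, out_v):
    """Backward Euler for one AP-family cell (damped Newton, analytic 2x2
    Jacobian).  Returns (u, v, status, max_iters_used)."""
    u, v = u0, v0
    j = 0
    if out_u.shape[0] > 0:
        out_u[0] = u
        out_v[0] = v
        j = 1
    worst = 0
    for s in range(n_steps):
        un, vn = u, v  # Newton iterate, warm-started at the old state
        it = 0
        converged = False
        while it < max_inner:
            du, dv = _ap_rates(un, vn, k, a, b, e0, m1, m2, ct)
            fu = un - u - dt * (du + i_ext)
            fv = vn - v - dt * dv
            r = max(abs(fu), abs(fv))
            if r < abs_tol and it > 0:
                converged = True
                break
            juu, juv, jvu, jvv = _ap_jac(un, vn, k, a, b, e0, m1, m2, ct)
            a11 = 1.0 - dt * juu
            a12 = -dt * juv
            a21 = -dt * jvu
            a22 = 1.0 - dt * jvv
            det = a11 * a22 - a12 * a21
            if det == 0.0 or not np.isfinite(det):
                return un, vn, DIVERGED, worst
            su = (-fu * a22 + fv * a12) / det
            sv = (-fv * a11 + fu * a21) / det
            lam = 1.0
            for _ in range(6):
                ut, vt = un + lam * su, vn + lam * sv
                dut, dvt = _ap_rates(ut, vt, k, a, b, e0, m1, m2, ct)
                fut = ut - u - dt * (dut + i_ext)
                fvt = vt - v - dt * dvt
                if np.isfinite(fut) and np.isfinite(fvt) and \
                        max(abs(fut), abs(fvt)) <= r:
                    break
                lam *= 0.5
            un += lam * su
            vn += lam * sv
            it += 1
        if not converged:
            # accept only if the final residual actually meets the tolerance
            du, dv = _ap_rates(un, vn, k, a, b, e0, m1, m2, ct)
            if max(abs(un - u - dt * (du + i_ext)), abs(vn - v - dt * dv)) >= abs_tol:
                return un, vn, NO_CONVERGENCE, max_inner
        if it > worst:
            worst = it
        u, v = un, vn
        if not (np.isfinite(u) and np.isfinite(v)):
            return u, v, DIVERGED, worst
        if (s + 1) % rec_every == 0 and j < out_u.shape[0]:
            out_u[j] = u
            out_v[j] = v
            j += 1
    return u, v, OK, worst


@njit(cache=True)
def cn_cell_fe(u0, h0, tin, tout, topen, tclose, ugate, us, b, tsgn, i_ext, dt,
               n_steps, rec_every, out_u, out_h):
    u, h = u0, h0
    j = 0
    if out_u.shape[0] > 0:
        out_u[0] = u
        out_h[0] = h
        j = 1
    for s in range(n_steps):
        du, dh = _cn_rates(u, h, tin, tout, topen, tclose, ugate, us, b, tsgn)
        u += dt * (du + i_ext)
        h += dt * dh
        if not (np.isfinite(u) and np.isfinite(h)):
            return u, h, DIVERGED
        if (s + 1) % rec_every == 0 and j < out_u.shape[0]:
            out_u[j] = u
            out_h[j] = h
            j += 1
    return u, h, OK


@njit(cache=True)
def cn_cell_be(u0, h0, tin, tout, topen, tclose, ugate, us, b, tsgn, i_ext, dt,
               n_steps, abs_tol, max_inner, rec_every, out_u, out_h):
    u, h = u0, h0
    j = 0
    if out_u.shape[0] > 0:
        out_u[0] = u
        out_h[0] = h
        j = 1
    worst = 0
    for s in range(n_steps):
        un, hn = u, h
        it = 0
        converged = False
        while it < max_inner:
            du, dh = _cn_rates(un, hn, tin, tout, topen, tclose, ugate, us, b, tsgn)
            fu = un - u - dt * (du + i_ext)
            fh = hn - h - dt * dh
            r = max(abs(fu), abs(fh))
            if r < abs_tol and it > 0:
                converged = True
                break
            juu, juh, jhu, jhh = _cn_jac(un, hn, tin, tout, topen, tclose, ugate, us, b, tsgn)
            a11 = 1.0 - dt * juu
            a12 = -dt * juh
            a21 = -dt * jhu
            a22 = 1.0 - dt * jhh
            det = a11 * a22 - a12 * a21
            if det == 0.0 or not np.isfinite(det):
                return un, hn, DIVERGED, worst
            su = (-fu * a22 + fh * a12) / det
            sh = (-fh * a11 + fu * a21) / det
            lam = 1.0
            for _ in range(6):
                ut, ht = un + lam * su, hn + lam * sh
                dut, dht = _cn_rates(ut, ht, tin, tout, topen, tclose, ugate, us, b, tsgn)
                fut = ut - u - dt * (dut + i_ext)
                fht = ht - h - dt * dht
                if np.isfinite(fut) and np.isfinite(fht) and \
                        max(abs(fut), abs(fht)) <= r:
                    break
                lam *= 0.5
            un += lam * su
            hn += lam * sh
            it += 1
        if not converged:
            du, dh = _cn_rates(un, hn, tin, tout, topen, tclose, ugate, us, b, tsgn)
            if max(abs(un - u - dt * (du + i_ext)), abs(hn - h - dt * dh)) >= abs_tol:
                return un, hn, NO_CONVERGENCE, max_inner
        if it > worst:
            worst = it
        u, h = un, hn
        if not (np.isfinite(u) and np.isfinite(h)):
            return u, h, DIVERGED, worst
        if (s + 1) % rec_every == 0 and j < out_u.shape[0]:
            out_u[j] = u
            out_h[j] = h
            j += 1
    return u, h, OK, worst


# ---------------------------------------------------------------------------
# tissue integrators (forward Euler; backward Euler is operator-split at the
# Python level with the pointwise implicit-reaction kernels below)
# ---------------------------------------------------------------------------

KIND_AP = 0
KIND_PASSIVE = 1


@njit(cache=True)
def cardiac_tissue_fe(u, v, kind, P, indptr, indices, data, dt, n_steps, t0,
                      rec_idx, rec_every, out_u, out_v,
                      cross_level, cross_times, cross_count):
    """Forward Euler on a cardiac-family tissue.  Mutates ``u``/``v`` in place.

    Records ``u``/``v`` at nodes ``rec_idx`` every ``rec_every`` steps, and for
    every node the times of upward crossings of ``cross_level`` (up to the
    capacity of ``cross_times``; ``cross_count`` keeps counting past it).
    Returns (status, bad_node, step_of_failure).
    """
    n = u.shape[0]
    du = np.empty(n)
    dv = np.empty(n)
    j = 0
    if out_u.shape[0] > 0:
        for q in range(rec_idx.shape[0]):
            out_u[0, q] = u[rec_idx[q]]
            out_v[0, q] = v[rec_idx[q]]
        j = 1
    cap = cross_times.shape[1]
    for s in range(n_steps):
        for i in range(n):
            # coupling current: row of the CSR operator applied to u
            acc = 0.0
            for p in range(indptr[i], indptr[i + 1]):
                acc += data[p] * u[indices[p]]
            if kind[i] == KIND_AP:
                ru, rv = _ap_rates(u[i], v[i], P[i, 0], P[i, 1], P[i, 2],
                                   P[i, 3], P[i, 4], P[i, 5], P[i, 6])
            else:
                ru = -P[i, 6] * P[i, 0] * u[i]
                rv = 0.0
            du[i] = ru + acc
            dv[i] = rv
        for i in range(n):
            un = u[i] + dt * du[i]
            if not np.isfinite(un):
                return DIVERGED, i, s
            if u[i] < cross_level and un >= cross_level:
                c = cross_count[i]
                if c < cap:
                    # linear interpolation of the crossing instant
                    frac = (cross_level - u[i]) / (un - u[i])
                    cross_times[i, c] = t0 + (s + frac) * dt
                cross_count[i] = c + 1
            u[i] = un
            v[i] += dt * dv[i]
        if (s + 1) % rec_every == 0 and j < out_u.shape[0]:
            for q in range(rec_idx.shape[0]):
                out_u[j, q] = u[rec_idx[q]]
                out_v[j, q] = v[rec_idx[q]]
            j += 1
    return OK, -1, n_steps


@njit(cache=True)
def gut_tissue_fe(u, h, P, indptr, indices, data, dt, n_steps, t0,
                  rec_idx, rec_every, out_u, out_h,
                  cross_level, cross_times, cross_count):
    """Forward Euler on a gut-family (Corrado) tissue; see cardiac_tissue_fe."""
    n = u.shape[0]
    du = np.empty(n)
    dh = np.empty(n)
    j = 0
    if out_u.shape[0] > 0:
        for q in range(rec_idx.shape[0]):
            out_u[0, q] = u[rec_idx[q]]
            out_h[0, q] = h[rec_idx[q]]
        j = 1
    cap = cross_times.shape[1]
    for s in range(n_steps):
        for i in range(n):
            acc = 0.0
            for p in range(indptr[i], indptr[i + 1]):
                acc += data[p] * u[indices[p]]
            ru, rh = _cn_rates(u[i], h[i], P[i, 0], P[i, 1], P[i, 2],
                               P[i, 3], P[i, 4], P[i, 5], P[i, 6], P[i, 7])
            du[i] = ru + acc
            dh[i] = rh
        for i in range(n):
            un = u[i] + dt * du[i]
            if not np.isfinite(un):
                return DIVERGED, i, s
            if u[i] < cross_level and un >= cross_level:
                c = cross_count[i]
                if c < cap:
                    frac = (cross_level - u[i]) / (un - u[i])
                    cross_times[i, c] = t0 + (s + frac) * dt
                cross_count[i] = c + 1
            u[i] = un
            h[i] += dt * dh[i]
        if (s + 1) % rec_every == 0 and j < out_u.shape[0]:
            for q in range(rec_idx.shape[0]):
                out_u[j, q] = u[rec_idx[q]]
                out_h[j, q] = h[rec_idx[q]]
            j += 1
    return OK, -1, n_steps


@njit(cache=True)
def cardiac_react_be(u, v, kind, P, i_ext, dt, abs_tol, max_inner):
    """One pointwise implicit (backward Euler) reaction step for every node of
    a cardiac-family tissue; ``i_ext`` is a frozen per-node coupling current.
    Returns (status, bad_node, max_iters_used)."""
    n = u.shape[0]
    worst = 0
    for i in range(n):
        if kind[i] == KIND_PASSIVE:
            # linear: closed-form implicit update
            u[i] = (u[i] + dt * i_ext[i]) / (1.0 + dt * P[i, 6] * P[i, 0])
            continue
        k, a, b, e0, m1, m2, ct = P[i, 0], P[i, 1], P[i, 2], P[i, 3], P[i, 4], P[i, 5], P[i, 6]
        u0, v0 = u[i], v[i]
        un, vn = u0, v0
        it = 0
        converged = False
        while it < max_inner:
            du, dv = _ap_rates(un, vn, k, a, b, e0, m1, m2, ct)
            fu = un - u0 - dt * (du + i_ext[i])
            fv = vn - v0 - dt * dv
            r = max(abs(fu), abs(fv))
            if r < abs_tol and it > 0:
                converged = True
                break
            juu, juv, jvu, jvv = _ap_jac(un, vn, k, a, b, e0, m1, m2, ct)
            a11 = 1.0 - dt * juu
            a12 = -dt * juv
            a21 = -dt * jvu
            a22 = 1.0 - dt * jvv
            det = a11 * a22 - a12 * a21
            if det == 0.0 or not np.isfinite(det):
                return DIVERGED, i, worst
            su = (-fu * a22 + fv * a12) / det
            sv = (-fv * a11 + fu * a21) / det
            lam = 1.0
            for _ in range(6):
                ut, vt = un + lam * su, vn + lam * sv
                dut, dvt = _ap_rates(ut, vt, k, a, b, e0, m1, m2, ct)
                fut = ut - u0 - dt * (dut + i_ext[i])
                fvt = vt - v0 - dt * dvt
                if np.isfinite(fut) and np.isfinite(fvt) and \
                        max(abs(fut), abs(fvt)) <= r:
                    break
                lam *= 0.5
            un += lam * su
            vn += lam * sv
            it += 1
        if not converged:
            du, dv = _ap_rates(un, vn, k, a, b, e0, m1, m2, ct)
            if max(abs(un - u0 - dt * (du + i_ext[i])), abs(vn - v0 - dt * dv)) >= abs_tol:
                return NO_CONVERGENCE, i, max_inner
        if it > worst:
            worst = it
        u[i], v[i] = un, vn
    return OK, -1, worst


@njit(cache=True)
def gut_react_be(u, h, P, i_ext, dt, abs_tol, max_inner):
    """Pointwise implicit reaction step for a gut-family tissue."""
    n = u.shape[0]
    worst = 0
    for i in range(n):
        tin, tout, topen, tclose = P[i, 0], P[i, 1], P[i, 2], P[i, 3]
        ugate, us, b, tsgn = P[i, 4], P[i, 5], P[i, 6], P[i, 7]
        u0, h0 = u[i], h[i]
        un, hn = u0, h0
        it = 0
        converged = False
        while it < max_inner:
            du, dh = _cn_rates(un, hn, tin, tout, topen, tclose, ugate, us, b, tsgn)
            fu = un - u0 - dt * (du + i_ext[i])
            fh = hn - h0 - dt * dh
            r = max(abs(fu), abs(fh))
            if r < abs_tol and it > 0:
                converged = True
                break
            juu, juh, jhu, jhh = _cn_jac(un, hn, tin, tout, topen, tclose, ugate, us, b, tsgn)
            a11 = 1.0 - dt * juu
            a12 = -dt * juh
            a21 = -dt * jhu
            a22 = 1.0 - dt * jhh
            det = a11 * a22 - a12 * a21
            if det == 0.0 or not np.isfinite(det):
                return DIVERGED, i, worst
            su = (-fu * a22 + fh * a12) / det
            sh = (-fh * a11 + fu * a21) / det
            lam = 1.0
            for _ in range(6):
                ut, ht = un + lam * su, hn + lam * sh
                dut, dht = _cn_rates(ut, ht, tin, tout, topen, tclose, ugate, us, b, tsgn)
                fut = ut - u0 - dt * (dut + i_ext[i])
                fht = ht - h0 - dt * dht
                if np.isfinite(fut) and np.isfinite(fht) and \
                        max(abs(fut), abs(fht)) <= r:
                    break
                lam *= 0.5
            un += lam * su
            hn += lam * sh
            it += 1
        if not converged:
            du, dh = _cn_rates(un, hn, tin, tout, topen, tclose, ugate, us, b, tsgn)
            if max(abs(un - u0 - dt * (du + i_ext[i])), abs(hn - h0 - dt * dh)) >= abs_tol:
                return NO_CONVERGENCE, i, max_inner
        if it > worst:
            worst = it
        u[i], h[i] = un, hn
    return OK, -1, worst


@njit(cache=True)
def cardiac_tissue_be(u, v, kind, P, indptr, indices, data, Minv, dt, n_steps,
                      t0, rec_idx, rec_every, out_u, out_v,
                      cross_level, cross_times, cross_count,
                      abs_tol, max_inner):
    """Operator-split backward Euler with a dense inverse of (I - dt*L) for
    small systems: implicit pointwise reaction (coupling frozen), then
    implicit diffusion.  Returns (status, bad_node, step, max_iters_used)."""
    n = u.shape[0]
    j = 0
    if out_u.shape[0] > 0:
        for q in range(rec_idx.shape[0]):
            out_u[0, q] = u[rec_idx[q]]
            out_v[0, q] = v[rec_idx[q]]
        j = 1
    cap = cross_times.shape[1]
    i_ext = np.empty(n)
    u_prev = np.empty(n)
    worst = 0
    for s in range(n_steps):
        for i in range(n):
            acc = 0.0
            for p in range(indptr[i], indptr[i + 1]):
                acc += data[p] * u[indices[p]]
            i_ext[i] = acc
            u_prev[i] = u[i]
        status, bad, it = cardiac_react_be(u, v, kind, P, i_ext, dt,
                                           abs_tol, max_inner)
        if status != OK:
            return status, bad, s, worst
        if it > worst:
            worst = it
        # implicit diffusion around the frozen explicit coupling
        rhs = u - dt * i_ext
        un = Minv @ rhs
        for i in range(n):
            if not np.isfinite(un[i]):
                return DIVERGED, i, s, worst
            if u_prev[i] < cross_level and un[i] >= cross_level:
                c = cross_count[i]
                if c < cap:
                    frac = (cross_level - u_prev[i]) / (un[i] - u_prev[i])
                    cross_times[i, c] = t0 + (s + frac) * dt
                cross_count[i] = c + 1
            u[i] = un[i]
        if (s + 1) % rec_every == 0 and j < out_u.shape[0]:
            for q in range(rec_idx.shape[0]):
                out_u[j, q] = u[rec_idx[q]]
                out_v[j, q] = v[rec_idx[q]]
            j += 1
    return OK, -1, n_steps, worst


@njit(cache=True)
def gut_tissue_be(u, h, P, indptr, indices, data, Minv, dt, n_steps,
                  t0, rec_idx, rec_every, out_u, out_h,
                  cross_level, cross_times, cross_count,
                  abs_tol, max_inner):
    """Gut-family analogue of cardiac_tissue_be."""
    n = u.shape[0]
    j = 0
    if out_u.shape[0] > 0:
        for q in range(rec_idx.shape[0]):
            out_u[0, q] = u[rec_idx[q]]
            out_h[0, q] = h[rec_idx[q]]
        j = 1
    cap = cross_times.shape[1]
    i_ext = np.empty(n)
    u_prev = np.empty(n)
    worst = 0
    for s in range(n_steps):
        for i in range(n):
            acc = 0.0
            for p in range(indptr[i], indptr[i + 1]):
                acc += data[p] * u[indices[p]]
            i_ext[i] = acc
            u_prev[i] = u[i]
        status, bad, it = gut_react_be(u, h, P, i_ext, dt, abs_tol, max_inner)
        if status != OK:
            return status, bad, s, worst
        if it > worst:
            worst = it
        rhs = u - dt * i_ext
        un = Minv @ rhs
        for i in range(n):
            if not np.isfinite(un[i]):
                return DIVERGED, i, s, worst
            if u_prev[i] < cross_level and un[i] >= cross_level:
                c = cross_count[i]
                if c < cap:
                    frac = (cross_level - u_prev[i]) / (un[i] - u_prev[i])
                    cross_times[i, c] = t0 + (s + frac) * dt
                cross_count[i] = c + 1
            u[i] = un[i]
        if (s + 1) % rec_every == 0 and j < out_u.shape[0]:
            for q in range(rec_idx.shape[0]):
                out_u[j, q] = u[rec_idx[q]]
                out_h[j, q] = h[rec_idx[q]]
            j += 1
    return OK, -1, n_steps, worst
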