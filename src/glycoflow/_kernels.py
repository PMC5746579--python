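"""Numba kernels for the particle simulator.

The box is periodic in x and y only; z is bounded by the frozen wall and
ceiling lattices.  Pair lists exclude immobile-immobile pairs (frozen
particles never move, and the thermostat skips them).
"""

from __future__ import annotations

import numba as nb
import numpy as np


@nb.njit(cache=True)
def _build_pairs_impl(pos, mobile, Lx, Ly, Lz, rcut, cap):
    n = pos.shape[0]
    ncx = max(int(Lx / rcut), 1)
    ncy = max(int(Ly / rcut), 1)
    ncz = max(int(Lz / rcut), 1)
    cw_x, cw_y, cw_z = Lx / ncx, Ly / ncy, Lz / ncz
    ncells = ncx * ncy * ncz

    head = np.full(ncells, -1, np.int64)
    nxt = np.full(n, -1, np.int64)
    cix = np.empty(n, np.int64)
    ciy = np.empty(n, np.int64)
    ciz = np.empty(n, np.int64)
    for i in range(n):
        ix = int(pos[i, 0] / cw_x) % ncx
        iy = int(pos[i, 1] / cw_y) % ncy
        iz = int(pos[i, 2] / cw_z)
        if iz < 0:
            iz = 0
        elif iz >= ncz:
            iz = ncz - 1
        cix[i], ciy[i], ciz[i] = ix, iy, iz
        c = (ix * ncy + iy) * ncz + iz
        nxt[i] = head[c]
        head[c] = i

    pi = np.empty(cap, np.int64)
    pj = np.empty(cap, np.int64)
    npair = 0
    r2cut = rcut * rcut
    for i in range(n):
        for dx in range(-1, 2):
            jx = (cix[i] + dx) % ncx
            for dy in range(-1, 2):
                jy = (ciy[i] + dy) % ncy
                for dz in range(-1, 2):
                    jz = ciz[i] + dz
                    if jz < 0 or jz >= ncz:
                        continue
                    j = head[(jx * ncy + jy) * ncz + jz]
                    while j >= 0:
                        if j > i and (mobile[i] or mobile[j]):
                            ddx = pos[i, 0] - pos[j, 0]
                            ddx -= Lx * np.rint(ddx / Lx)
                            ddy = pos[i, 1] - pos[j, 1]
                            ddy -= Ly * np.rint(ddy / Ly)
                            ddz = pos[i, 2] - pos[j, 2]
                            r2 = ddx * ddx + ddy * ddy + ddz * ddz
                            if r2 < r2cut:
                                if npair >= cap:
                                    return pi, pj, -1
                                pi[npair] = i
                                pj[npair] = j
                                npair += 1
                        j = nxt[j]
    return pi, pj, npair


def build_pairs(pos, mobile, box, rcut):
    """Half pair list (i < j) within ``rcut``, sorted lexicographically.

    Cells with ``ncx/ncy < 3`` would double-count periodic neighbours with a
    full 27-stencil, so the cell width is clamped to at least a third of the
    box in x and y by the caller choosing ``rcut <= min(Lx, Ly) / 3``.
    """
    Lx, Ly, Lz = float(box[0]), float(box[1]), float(box[2])
    if rcut > min(Lx, Ly) / 3.0:
        raise ValueError(
            f"pair cut-off {rcut} exceeds a third of the periodic box "
            f"({min(Lx, Ly)}); enlarge the box or reduce the cut-off")
    cap = max(64 * pos.shape[0], 4096)
    while True:
        pi, pj, npair = _build_pairs_impl(
            np.ascontiguousarray(pos), mobile, Lx, Ly, Lz, rcut, cap)
        if npair >= 0:
            break
        cap *= 2
    pi, pj = pi[:npair], pj[:npair]
    order = np.lexsort((pj, pi))
    return np.ascontiguousarray(pi[order]), np.ascontiguousarray(pj[order])


@nb.njit(cache=True)
def wca_forces(pos, pi, pj, Lx, Ly, rc2, sigma2, eps, F):
    """Purely repulsive (WCA) pair forces; returns the minimum pair r^2."""
    min_r2 = 1.0e30
    for k in range(pi.shape[0]):
        i, j = pi[k], pj[k]
        dx = pos[i, 0] - pos[j, 0]
        dx -= Lx * np.rint(dx / Lx)
        dy = pos[i, 1] - pos[j, 1]
        dy -= Ly * np.rint(dy / Ly)
        dz = pos[i, 2] - pos[j, 2]
        r2 = dx * dx + dy * dy + dz * dz
        if r2 < rc2 and r2 > 0.0:
            if r2 < min_r2:
                min_r2 = r2
            s2 = sigma2 / r2
            s6 = s2 * s2 * s2
            fmag = 24.0 * eps * (2.0 * s6 * s6 - s6) / r2
            fx, fy, fz = fmag * dx, fmag * dy, fmag * dz
            F[i, 0] += fx
            F[i, 1] += fy
            F[i, 2] += fz
            F[j, 0] -= fx
            F[j, 1] -= fy
            F[j, 2] -= fz
    return min_r2


@nb.njit(cache=True)
def bond_forces(pos, bi, bj, r0, kb, Lx, Ly, F):
    for k in range(bi.shape[0]):
        i, j = bi[k], bj[k]
        dx = pos[i, 0] - pos[j, 0]
        dx -= Lx * np.rint(dx / Lx)
        dy = pos[i, 1] - pos[j, 1]
        dy -= Ly * np.rint(dy / Ly)
        dz = pos[i, 2] - pos[j, 2]
        r = np.sqrt(dx * dx + dy * dy + dz * dz)
        if r > 0.0:
            fmag = -kb[k] * (r - r0[k]) / r
            fx, fy, fz = fmag * dx, fmag * dy, fmag * dz
            F[i, 0] += fx
            F[i, 1] += fy
            F[i, 2] += fz
            F[j, 0] -= fx
            F[j, 1] -= fy
            F[j, 2] -= fz


@nb.njit(cache=True)
def angle_forces(pos, ai, aj, ak, ka, Lx, Ly, F):
    """Straightening potential U = k (1 + cos theta) on (i, j, k) triples."""
    for t in range(ai.shape[0]):
        i, j, k = ai[t], aj[t], ak[t]
        ax = pos[i, 0] - pos[j, 0]
        ax -= Lx * np.rint(ax / Lx)
        ay = pos[i, 1] - pos[j, 1]
        ay -= Ly * np.rint(ay / Ly)
        az = pos[i, 2] - pos[j, 2]
        bx = pos[k, 0] - pos[j, 0]
        bx -= Lx * np.rint(bx / Lx)
        by = pos[k, 1] - pos[j, 1]
        by -= Ly * np.rint(by / Ly)
        bz = pos[k, 2] - pos[j, 2]
        la2 = ax * ax + ay * ay + az * az
        lb2 = bx * bx + by * by + bz * bz
        if la2 <= 0.0 or lb2 <= 0.0:
            continue
        la = np.sqrt(la2)
        lb = np.sqrt(lb2)
        cosq = (ax * bx + ay * by + az * bz) / (la * lb)
        # F_i = -k * d(cos theta)/d r_i ; F_k symmetric; F_j balances.
        gix = -ka[t] * (bx / (la * lb) - cosq * ax / la2)
        giy = -ka[t] * (by / (la * lb) - cosq * ay / la2)
        giz = -ka[t] * (bz / (la * lb) - cosq * az / la2)
        gkx = -ka[t] * (ax / (la * lb) - cosq * bx / lb2)
        gky = -ka[t] * (ay / (la * lb) - cosq * by / lb2)
        gkz = -ka[t] * (az / (la * lb) - cosq * bz / lb2)
        F[i, 0] += gix
        F[i, 1] += giy
        F[i, 2] += giz
        F[k, 0] += gkx
        F[k, 1] += gky
        F[k, 2] += gkz
        F[j, 0] -= gix + gkx
        F[j, 1] -= giy + gky
        F[j, 2] -= giz + gkz


@nb.njit(cache=True)
def tether_forces(pos, idx, anchors, kt, Lx, Ly, F):
    for k in range(idx.shape[0]):
        i = idx[k]
        dx = pos[i, 0] - anchors[k, 0]
        dx -= Lx * np.rint(dx / Lx)
        dy = pos[i, 1] - anchors[k, 1]
        dy -= Ly * np.rint(dy / Ly)
        dz = pos[i, 2] - anchors[k, 2]
        F[i, 0] -= kt[k] * dx
        F[i, 1] -= kt[k] * dy
        F[i, 2] -= kt[k] * dz


@nb.njit(cache=True)
def lowe_andersen(pos, vel, mass, mobile, pi, pj, Lx, Ly, rc2,
                  gamma_dt, T, u_rand, g_rand):
    """Pairwise velocity resampling, visited in the given (sorted) order.

    Mobile-mobile pairs exchange momentum symmetrically (conserved exactly);
    a mobile particle colliding with a frozen wall/ceiling particle is
    treated as hitting an infinite mass, which thermalises the boundary and
    provides the no-slip momentum sink.
    """
    n_coll = 0
    for k in range(pi.shape[0]):
        if u_rand[k] >= gamma_dt:
            continue
        i, j = pi[k], pj[k]
        if not mobile[i] and not mobile[j]:
            continue
        dx = pos[i, 0] - pos[j, 0]
        dx -= Lx * np.rint(dx / Lx)
        dy = pos[i, 1] - pos[j, 1]
        dy -= Ly * np.rint(dy / Ly)
        dz = pos[i, 2] - pos[j, 2]
        r2 = dx * dx + dy * dy + dz * dz
        if r2 >= rc2 or r2 <= 0.0:
            continue
        inv_r = 1.0 / np.sqrt(r2)
        ex, ey, ez = dx * inv_r, dy * inv_r, dz * inv_r
        if mobile[i] and mobile[j]:
            mu = mass[i] * mass[j] / (mass[i] + mass[j])
            vrel = ((vel[i, 0] - vel[j, 0]) * ex
                    + (vel[i, 1] - vel[j, 1]) * ey
                    + (vel[i, 2] - vel[j, 2]) * ez)
            xi = g_rand[k] * np.sqrt(T / mu)
            d = xi - vrel
            ci = mu / mass[i]
            cj = mu / mass[j]
            vel[i, 0] += ci * d * ex
            vel[i, 1] += ci * d * ey
            vel[i, 2] += ci * d * ez
            vel[j, 0] -= cj * d * ex
            vel[j, 1] -= cj * d * ey
            vel[j, 2] -= cj * d * ez
        else:
            a = i if mobile[i] else j
            va = vel[a, 0] * ex + vel[a, 1] * ey + vel[a, 2] * ez
            xi = g_rand[k] * np.sqrt(T / mass[a])
            d = xi - va
            vel[a, 0] += d * ex
            vel[a, 1] += d * ey
            vel[a, 2] += d * ez
        n_coll += 1
    return n_coll
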