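"""Numba kernels: cell-list pair forces and the Langevin integrator core.

The cell list covers the monomer-monomer WCA interaction (cutoff
2^(1/6) sigma); condensin-condensin attraction is evaluated all-pairs
(condensin counts are tiny compared to monomer counts).  No periodic
boundaries: the system lives in open space.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

__all__ = ["wca_pair", "forces_kernel", "energy_kernel", "baoab_chunk"]


@njit(cache=True)
def _wca_consts(sigma, eps, eps_cut):
    """Return (r_cut2, r_cap, f_cap)."""
    r_cut = 2.0 ** (1.0 / 6.0) * sigma
    x = 0.5 + math.sqrt(eps_cut / (4.0 * eps))
    r_cap = sigma * x ** (-1.0 / 6.0)
    sr6 = (sigma / r_cap) ** 6
    f_cap = 24.0 * eps / r_cap * (2.0 * sr6 * sr6 - sr6)
    return r_cut * r_cut, r_cap, f_cap


@njit(cache=True)
def wca_pair(r, sigma, eps, eps_cut, cap_linear):
    """Capped WCA energy and radial force magnitude (positive = repulsive).

    Coincident particles (r ~ 0) return the clamped energy with zero force
    so pathological starting configurations survive.
    """
    r_cut2, r_cap, f_cap = _wca_consts(sigma, eps, eps_cut)
    if r * r >= r_cut2:
        return 0.0, 0.0
    if r < r_cap:
        if cap_linear and r > 0.0:
            return eps_cut + f_cap * (r_cap - r), f_cap
        return eps_cut, 0.0
    sr6 = (sigma / r) ** 6
    u = 4.0 * eps * (sr6 * sr6 - sr6 + 0.25)
    f = 24.0 * eps / r * (2.0 * sr6 * sr6 - sr6)
    return u, f


@njit(cache=True)
def _cell_grid(pos, rc):
    """Assign particles to cells of side >= rc; linked-list storage.

    Returns (head, nxt, cell_index_of_particle, ncx, ncy, ncz, mins, inv_w).
    """
    n = pos.shape[0]
    mins = np.empty(3)
    maxs = np.empty(3)
    for d in range(3):
        mn = pos[0, d]
        mx = pos[0, d]
        for i in range(1, n):
            v = pos[i, d]
            if v < mn:
                mn = v
            if v > mx:
                mx = v
        mins[d] = mn
        maxs[d] = mx
    nc = np.empty(3, dtype=np.int64)
    for d in range(3):
        ext = maxs[d] - mins[d]
        ratio = ext / rc
        # blown-up or non-finite coordinates: fall back to a single cell
        # (all-pairs scan); the caller's finiteness check reports the error
        if not (ratio < 1e9):
            ratio = 1.0
        k = int(ratio)
        if k < 1:
            k = 1
        nc[d] = k
    # bound total cell count by ~8n
    while nc[0] * nc[1] * nc[2] > 8 * n + 64:
        dmax = 0
        if nc[1] > nc[dmax]:
            dmax = 1
        if nc[2] > nc[dmax]:
            dmax = 2
        nc[dmax] = (nc[dmax] + 1) // 2
    inv_w = np.empty(3)
    for d in range(3):
        ext = maxs[d] - mins[d]
        if ext <= 0.0:
            inv_w[d] = 0.0
        else:
            inv_w[d] = nc[d] / ext * (1.0 - 1e-12)
    ncells = nc[0] * nc[1] * nc[2]
    head = np.full(ncells, -1, dtype=np.int64)
    nxt = np.empty(n, dtype=np.int64)
    cidx = np.empty((n, 3), dtype=np.int64)
    for i in range(n):
        ix = int((pos[i, 0] - mins[0]) * inv_w[0])
        iy = int((pos[i, 1] - mins[1]) * inv_w[1])
        iz = int((pos[i, 2] - mins[2]) * inv_w[2])
        cidx[i, 0] = ix
        cidx[i, 1] = iy
        cidx[i, 2] = iz
        c = (ix * nc[1] + iy) * nc[2] + iz
        nxt[i] = head[c]
        head[c] = i
    return head, nxt, cidx, nc


@njit(cache=True)
def forces_kernel(mon_pos, cond_pos, springs, anchors,
                  sigma, eps, eps_cut, cap_linear,
                  eps_spr, d_B, F_loop, F_cond, Delta,
                  conf_R, conf_k, conf_fmax, conf_center,
                  f_mon, f_cond):
    n = mon_pos.shape[0]
    r_cut2, r_cap, f_cap = _wca_consts(sigma, eps, eps_cut)
    rc = math.sqrt(r_cut2)
    # --- monomer-monomer WCA via cell list ---
    head, nxt, cidx, nc = _cell_grid(mon_pos, rc)
    for i in range(n):
        xi = mon_pos[i, 0]
        yi = mon_pos[i, 1]
        zi = mon_pos[i, 2]
        for ox in range(-1, 2):
            cx = cidx[i, 0] + ox
            if cx < 0 or cx >= nc[0]:
                continue
            for oy in range(-1, 2):
                cy = cidx[i, 1] + oy
                if cy < 0 or cy >= nc[1]:
                    continue
                for oz in range(-1, 2):
                    cz = cidx[i, 2] + oz
                    if cz < 0 or cz >= nc[2]:
                        continue
                    j = head[(cx * nc[1] + cy) * nc[2] + cz]
                    while j >= 0:
                        if j > i:
                            dx = xi - mon_pos[j, 0]
                            dy = yi - mon_pos[j, 1]
                            dz = zi - mon_pos[j, 2]
                            r2 = dx * dx + dy * dy + dz * dz
                            if r2 < r_cut2:
                                r = math.sqrt(r2)
                                if r < r_cap:
                                    if cap_linear and r > 0.0:
                                        fr = f_cap / r
                                    else:
                                        fr = 0.0
                                else:
                                    sr6 = (sigma * sigma / r2) ** 3
                                    fr = 24.0 * eps / r2 * (2.0 * sr6 * sr6 - sr6)
                                f_mon[i, 0] += fr * dx
                                f_mon[i, 1] += fr * dy
                                f_mon[i, 2] += fr * dz
                                f_mon[j, 0] -= fr * dx
                                f_mon[j, 1] -= fr * dy
                                f_mon[j, 2] -= fr * dz
                        j = nxt[j]
    # --- springs (harmonic, phantom: no excluded volume of their own) ---
    for s in range(springs.shape[0]):
        a = springs[s, 0]
        b = springs[s, 1]
        dx = mon_pos[a, 0] - mon_pos[b, 0]
        dy = mon_pos[a, 1] - mon_pos[b, 1]
        dz = mon_pos[a, 2] - mon_pos[b, 2]
        r = math.sqrt(dx * dx + dy * dy + dz * dz)
        if r > 0.0:
            fr = -eps_spr * (r - d_B) / r
            f_mon[a, 0] += fr * dx
            f_mon[a, 1] += fr * dy
            f_mon[a, 2] += fr * dz
            f_mon[b, 0] -= fr * dx
            f_mon[b, 1] -= fr * dy
            f_mon[b, 2] -= fr * dz
    # --- loop-holding: condensin tied to its two anchors ---
    m = cond_pos.shape[0]
    if anchors.shape[0] == m:
        for c in range(m):
            for k in range(2):
                a = anchors[c, k]
                dx = cond_pos[c, 0] - mon_pos[a, 0]
                dy = cond_pos[c, 1] - mon_pos[a, 1]
                dz = cond_pos[c, 2] - mon_pos[a, 2]
                f_cond[c, 0] -= F_loop * dx
                f_cond[c, 1] -= F_loop * dy
                f_cond[c, 2] -= F_loop * dz
                f_mon[a, 0] += F_loop * dx
                f_mon[a, 1] += F_loop * dy
                f_mon[a, 2] += F_loop * dz
    # --- inter-condensin attraction (all pairs, cis and trans) ---
    if F_cond > 0.0 and Delta > 0.0:
        d2max = Delta * Delta
        for i in range(m):
            for j in range(i + 1, m):
                dx = cond_pos[i, 0] - cond_pos[j, 0]
                dy = cond_pos[i, 1] - cond_pos[j, 1]
                dz = cond_pos[i, 2] - cond_pos[j, 2]
                r2 = dx * dx + dy * dy + dz * dz
                if r2 < d2max and r2 > 0.0:
                    r = math.sqrt(r2)
                    fr = -2.0 * F_cond * (Delta - r) / r
                    f_cond[i, 0] += fr * dx
                    f_cond[i, 1] += fr * dy
                    f_cond[i, 2] += fr * dz
                    f_cond[j, 0] -= fr * dx
                    f_cond[j, 1] -= fr * dy
                    f_cond[j, 2] -= fr * dz
    # --- spherical confinement wall on monomers (compaction stage only) ---
    if conf_R > 0.0:
        for i in range(n):
            dx = mon_pos[i, 0] - conf_center[0]
            dy = mon_pos[i, 1] - conf_center[1]
            dz = mon_pos[i, 2] - conf_center[2]
            r = math.sqrt(dx * dx + dy * dy + dz * dz)
            if r > conf_R:
                mag = conf_k * (r - conf_R)
                if mag > conf_fmax:
                    mag = conf_fmax
                fr = -mag / r
                f_mon[i, 0] += fr * dx
                f_mon[i, 1] += fr * dy
                f_mon[i, 2] += fr * dz


@njit(cache=True)
def energy_kernel(mon_pos, cond_pos, springs, anchors,
                  sigma, eps, eps_cut, cap_linear,
                  eps_spr, d_B, F_loop, F_cond, Delta,
                  conf_R, conf_k, conf_fmax, conf_center):
    n = mon_pos.shape[0]
    r_cut2, r_cap, f_cap = _wca_consts(sigma, eps, eps_cut)
    rc = math.sqrt(r_cut2)
    u = 0.0
    head, nxt, cidx, nc = _cell_grid(mon_pos, rc)
    for i in range(n):
        for ox in range(-1, 2):
            cx = cidx[i, 0] + ox
            if cx < 0 or cx >= nc[0]:
                continue
            for oy in range(-1, 2):
                cy = cidx[i, 1] + oy
                if cy < 0 or cy >= nc[1]:
                    continue
                for oz in range(-1, 2):
                    cz = cidx[i, 2] + oz
                    if cz < 0 or cz >= nc[2]:
                        continue
                    j = head[(cx * nc[1] + cy) * nc[2] + cz]
                    while j >= 0:
                        if j > i:
                            dx = mon_pos[i, 0] - mon_pos[j, 0]
                            dy = mon_pos[i, 1] - mon_pos[j, 1]
                            dz = mon_pos[i, 2] - mon_pos[j, 2]
                            r2 = dx * dx + dy * dy + dz * dz
                            if r2 < r_cut2:
                                r = math.sqrt(r2)
                                if r < r_cap:
                                    if cap_linear and r > 0.0:
                                        u += eps_cut + f_cap * (r_cap - r)
                                    else:
                                        u += eps_cut
                                else:
                                    sr6 = (sigma * sigma / r2) ** 3
                                    u += 4.0 * eps * (sr6 * sr6 - sr6 + 0.25)
                        j = nxt[j]
    for s in range(springs.shape[0]):
        a = springs[s, 0]
        b = springs[s, 1]
        dx = mon_pos[a, 0] - mon_pos[b, 0]
        dy = mon_pos[a, 1] - mon_pos[b, 1]
        dz = mon_pos[a, 2] - mon_pos[b, 2]
        r = math.sqrt(dx * dx + dy * dy + dz * dz)
        u += 0.5 * eps_spr * (r - d_B) ** 2
    m = cond_pos.shape[0]
    if anchors.shape[0] == m:
        for c in range(m):
            for k in range(2):
                a = anchors[c, k]
                dx = cond_pos[c, 0] - mon_pos[a, 0]
                dy = cond_pos[c, 1] - mon_pos[a, 1]
                dz = cond_pos[c, 2] - mon_pos[a, 2]
                u += 0.5 * F_loop * (dx * dx + dy * dy + dz * dz)
    if F_cond > 0.0 and Delta > 0.0:
        d2max = Delta * Delta
        for i in range(m):
            for j in range(i + 1, m):
                dx = cond_pos[i, 0] - cond_pos[j, 0]
                dy = cond_pos[i, 1] - cond_pos[j, 1]
                dz = cond_pos[i, 2] - cond_pos[j, 2]
                r2 = dx * dx + dy * dy + dz * dz
                if r2 < d2max:
                    r = math.sqrt(r2)
                    u += -F_cond * (r - Delta) ** 2
    if conf_R > 0.0:
        for i in range(n):
            dx = mon_pos[i, 0] - conf_center[0]
            dy = mon_pos[i, 1] - conf_center[1]
            dz = mon_pos[i, 2] - conf_center[2]
            r = math.sqrt(dx * dx + dy * dy + dz * dz)
            if r > conf_R:
                ex = r - conf_R
                x_c = conf_fmax / conf_k
                if ex <= x_c:
                    u += 0.5 * conf_k * ex * ex
                else:
                    u += 0.5 * conf_k * x_c * x_c + conf_fmax * (ex - x_c)
    return u


@njit(cache=True)
def baoab_chunk(mon_pos, mon_vel, cond_pos, cond_vel,
                f_mon, f_cond,
                noise_mon, noise_cond,
                springs, anchors,
                dt, mass, c1, c2,
                sigma, eps, eps_cut, cap_linear,
                eps_spr, d_B, F_loop, F_cond, Delta,
                conf_R, conf_k, conf_fmax, conf_center):
    """Advance ``nsteps = noise_mon.shape[0]`` BAOAB Langevin steps in place.

    Splitting per step: B (half kick) - A (half drift) - O (exact
    Ornstein-Uhlenbeck velocity update) - A (half drift) - force
    recomputation - B (half kick).  With gamma = 0 the O step is the
    identity and the scheme reduces to plain velocity Verlet.
    ``f_mon``/``f_cond`` must hold the forces at the entry positions and
    hold the forces at the exit positions on return.
    """
    nsteps = noise_mon.shape[0]
    n = mon_pos.shape[0]
    m = cond_pos.shape[0]
    half = 0.5 * dt / mass
    halfdt = 0.5 * dt
    for s in range(nsteps):
        for i in range(n):
            for d in range(3):
                mon_vel[i, d] += half * f_mon[i, d]
                mon_pos[i, d] += halfdt * mon_vel[i, d]
                mon_vel[i, d] = c1 * mon_vel[i, d] + c2 * noise_mon[s, i, d]
                mon_pos[i, d] += halfdt * mon_vel[i, d]
        for i in range(m):
            for d in range(3):
                cond_vel[i, d] += half * f_cond[i, d]
                cond_pos[i, d] += halfdt * cond_vel[i, d]
                cond_vel[i, d] = c1 * cond_vel[i, d] + c2 * noise_cond[s, i, d]
                cond_pos[i, d] += halfdt * cond_vel[i, d]
        for i in range(n):
            for d in range(3):
                f_mon[i, d] = 0.0
        for i in range(m):
            for d in range(3):
                f_cond[i, d] = 0.0
        forces_kernel(mon_pos, cond_pos, springs, anchors,
                      sigma, eps, eps_cut, cap_linear,
                      eps_spr, d_B, F_loop, F_cond, Delta,
                      conf_R, conf_k, conf_fmax, conf_center,
                      f_mon, f_cond)
        for i in range(n):
            for d in range(3):
                mon_vel[i, d] += half * f_mon[i, d]
        for i in range(m):
            for d in range(3):
                cond_vel[i, d] += half * f_cond[i, d]
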