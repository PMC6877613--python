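"""Numba inner loops for the rod simulator.

Everything here works on plain float64/int arrays so the jitted code stays
cacheable and deterministic; the public API lives in ``rod_dynamics``.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# maximum contacts returned per call; dense packings at Phi <= 0.3 stay far
# below n * 6
_MAX_CONTACTS_PER_ROD = 16


@njit(cache=True)
def segment_closest(rx, ry, uxi, uyi, uxj, uyj, half_i, half_j):
    """Closest points between two centred segments.

    Segment i: s * (uxi, uyi), s in [-half_i, half_i], centred at origin.
    Segment j: (rx, ry) + t * (uxj, uyj), t in [-half_j, half_j].
    Returns (dist, s, t, vx, vy) where (vx, vy) points from the closest
    point on j to the closest point on i (unnormalized).
    Degenerate parallel overlaps use the midpoint of the overlap interval.
    """
    b = uxi * uxj + uyi * uyj
    d_ = -(uxi * rx + uyi * ry)   # u_i . (A - B) with A at origin: -(u_i . r)
    e_ = -(uxj * rx + uyj * ry)
    denom = 1.0 - b * b
    if denom > 1e-9:
        s = (b * e_ - d_) / denom
        if s > half_i:
            s = half_i
        elif s < -half_i:
            s = -half_i
        t = e_ + s * b
        if t > half_j:
            t = half_j
        elif t < -half_j:
            t = -half_j
        s = t * b - d_
        if s > half_i:
            s = half_i
        elif s < -half_i:
            s = -half_i
    else:
        # parallel rods: project segment j onto the axis of i
        p1 = -d_ + half_j * b
        p0 = -d_ - half_j * b
        if p0 > p1:
            p0, p1 = p1, p0
        lo = max(p0, -half_i)
        hi = min(p1, half_i)
        if lo <= hi:
            s = 0.5 * (lo + hi)
        elif p1 < -half_i:
            s = -half_i
        else:
            s = half_i
        t = (s + d_) * b  # b = +-1 for parallel segments
        if t > half_j:
            t = half_j
        elif t < -half_j:
            t = -half_j
        s = t * b - d_
        if s > half_i:
            s = half_i
        elif s < -half_i:
            s = -half_i
    vx = s * uxi - rx - t * uxj
    vy = s * uyi - ry - t * uyj
    dist = np.sqrt(vx * vx + vy * vy)
    return dist, s, t, vx, vy


@njit(cache=True)
def find_contacts_kernel(pos, ux, uy, box, seg_half, width):
    """All contacts (minimal image) as flat arrays.

    Returns (count, i_idx, j_idx, delta, unx, uny, li, lj) where (unx, uny)
    is the contact normal pointing from rod j to rod i and li/lj are the
    signed axial lever arms of the contact on each rod.
    """
    n = pos.shape[0]
    cap = _MAX_CONTACTS_PER_ROD * max(n, 1)
    i_idx = np.empty(cap, dtype=np.int64)
    j_idx = np.empty(cap, dtype=np.int64)
    delta = np.empty(cap)
    unx = np.empty(cap)
    uny = np.empty(cap)
    li = np.empty(cap)
    lj = np.empty(cap)

    reach = 2.0 * seg_half + width  # max centre distance of touching rods
    ncell = int(box / reach)
    if ncell < 3:
        ncell = 1
    count = 0
    if ncell == 1:
        for i in range(n):
            for j in range(i + 1, n):
                rx = pos[j, 0] - pos[i, 0]
                ry = pos[j, 1] - pos[i, 1]
                rx -= box * np.round(rx / box)
                ry -= box * np.round(ry / box)
                if rx * rx + ry * ry > reach * reach:
                    continue
                dist, s, t, vx, vy = segment_closest(
                    rx, ry, ux[i], uy[i], ux[j], uy[j], seg_half, seg_half)
                if dist < width:
                    if dist > 1e-9:
                        nx_, ny_ = vx / dist, vy / dist
                    else:
                        nx_, ny_ = -uy[i], ux[i]
                    i_idx[count] = i
                    j_idx[count] = j
                    delta[count] = width - dist
                    unx[count] = nx_
                    uny[count] = ny_
                    li[count] = s
                    lj[count] = t
                    count += 1
        return count, i_idx, j_idx, delta, unx, uny, li, lj

    cell_size = box / ncell
    head = -np.ones(ncell * ncell, dtype=np.int64)
    nxt = -np.ones(n, dtype=np.int64)
    for i in range(n):
        cx = int(pos[i, 0] / cell_size) % ncell
        cy = int(pos[i, 1] / cell_size) % ncell
        c = cx * ncell + cy
        nxt[i] = head[c]
        head[c] = i
    for i in range(n):
        cx = int(pos[i, 0] / cell_size) % ncell
        cy = int(pos[i, 1] / cell_size) % ncell
        for ox in range(-1, 2):
            for oy in range(-1, 2):
                c = ((cx + ox) % ncell) * ncell + ((cy + oy) % ncell)
                j = head[c]
                while j >= 0:
                    if j > i:
                        rx = pos[j, 0] - pos[i, 0]
                        ry = pos[j, 1] - pos[i, 1]
                        rx -= box * np.round(rx / box)
                        ry -= box * np.round(ry / box)
                        if rx * rx + ry * ry <= reach * reach:
                            dist, s, t, vx, vy = segment_closest(
                                rx, ry, ux[i], uy[i], ux[j], uy[j],
                                seg_half, seg_half)
                            if dist < width:
                                if dist > 1e-9:
                                    nx_, ny_ = vx / dist, vy / dist
                                else:
                                    nx_, ny_ = -uy[i], ux[i]
                                i_idx[count] = i
                                j_idx[count] = j
                                delta[count] = width - dist
                                unx[count] = nx_
                                uny[count] = ny_
                                li[count] = s
                                lj[count] = t
                                count += 1
                    j = nxt[j]
    return count, i_idx, j_idx, delta, unx, uny, li, lj


@njit(cache=True)
def steric_forces_kernel(count, i_idx, j_idx, delta, unx, uny, li, lj,
                         vel, ux, uy, K_el, K_fr):
    """Hertzian repulsion + tangential contact friction -> forces/torques.

    The friction uses the full rod velocities of the previous step.  Forces
    are pairwise antisymmetric; torques use the signed axial lever arm
    times the wedge product of the rod axis with the total contact force.
    """
    n = vel.shape[0]
    force = np.zeros((n, 2))
    torque = np.zeros(n)
    for k in range(count):
        i = i_idx[k]
        j = j_idx[k]
        fel = K_el * delta[k] ** 1.5
        fx = fel * unx[k]
        fy = fel * uny[k]
        # tangent: normal rotated by +90 deg
        tx = -uny[k]
        ty = unx[k]
        dvt = (vel[i, 0] - vel[j, 0]) * tx + (vel[i, 1] - vel[j, 1]) * ty
        fx -= K_fr * dvt * tx
        fy -= K_fr * dvt * ty
        force[i, 0] += fx
        force[i, 1] += fy
        force[j, 0] -= fx
        force[j, 1] -= fy
        torque[i] += li[k] * (ux[i] * fy - uy[i] * fx)
        torque[j] += lj[k] * (ux[j] * (-fy) - uy[j] * (-fx))
    return force, torque


@njit(cache=True)
def pairwise_flows_kernel(pos, ux, uy, fmag, L_dip, box,
                          table_r0, table_dr, table_A, table_B,
                          r_clamp, r_cutoff):
    """Dipole flow at each rod's two evaluation points, O(n^2) sum.

    fmag[j] is the signed magnitude of the propulsion force of rod j (zero
    while tumbling); the dipole is +F at the centre and -F a distance
    L_dip behind it.  The kernel factors A, B are linearly interpolated
    from the radial table; distances below r_clamp are clamped and beyond
    r_cutoff ignored.
    """
    n = pos.shape[0]
    w_centre = np.zeros((n, 2))
    w_rear = np.zeros((n, 2))
    ntab = table_A.shape[0]
    cut2 = r_cutoff * r_cutoff
    for i in range(n):
        ex0 = pos[i, 0]
        ey0 = pos[i, 1]
        ex1 = pos[i, 0] - L_dip * ux[i]
        ey1 = pos[i, 1] - L_dip * uy[i]
        for j in range(n):
            if j == i or fmag[j] == 0.0:
                continue
            fx = fmag[j] * ux[j]
            fy = fmag[j] * uy[j]
            for fp in range(2):
                if fp == 0:
                    px = pos[j, 0]
                    py = pos[j, 1]
                    sgn = 1.0
                else:
                    px = pos[j, 0] - L_dip * ux[j]
                    py = pos[j, 1] - L_dip * uy[j]
                    sgn = -1.0
                for ep in range(2):
                    if ep == 0:
                        dx = ex0 - px
                        dy = ey0 - py
                    else:
                        dx = ex1 - px
                        dy = ey1 - py
                    dx -= box * np.round(dx / box)
                    dy -= box * np.round(dy / box)
                    d2 = dx * dx + dy * dy
                    if d2 > cut2:
                        continue
                    d = np.sqrt(d2)
                    if d < r_clamp:
                        d = r_clamp
                        if d2 > 0.0:
                            scale = r_clamp / np.sqrt(d2)
                            dx *= scale
                            dy *= scale
                        else:
                            dx = r_clamp
                            dy = 0.0
                    pos_t = (d - table_r0) / table_dr
                    it = int(pos_t)
                    if it < 0:
                        it = 0
                    elif it > ntab - 2:
                        it = ntab - 2
                    wgt = pos_t - it
                    if wgt < 0.0:
                        wgt = 0.0
                    elif wgt > 1.0:
                        wgt = 1.0
                    A = table_A[it] * (1.0 - wgt) + table_A[it + 1] * wgt
                    B = table_B[it] * (1.0 - wgt) + table_B[it + 1] * wgt
                    rdotf = (dx * fx + dy * fy) / (d * d)
                    wx = sgn * (A * fx + B * rdotf * dx)
                    wy = sgn * (A * fy + B * rdotf * dy)
                    if ep == 0:
                        w_centre[i, 0] += wx
                        w_centre[i, 1] += wy
                    else:
                        w_rear[i, 0] += wx
                        w_rear[i, 1] += wy
    return w_centre, w_rear
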