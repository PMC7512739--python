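"""Numba kernels for pair forces of truncated-and-shifted LJ fluids.

Both kernels return (forces, potential_energy, virial) where the virial is
sum over pairs of r . F(r); they must agree to additive 1e-10 per component
(the cell-list path is guarded by the brute-force oracle in the tests).
Positions must be wrapped into [0, box), which lets the minimum image be a
single half-box comparison per axis.
"""

from __future__ import annotations

import numba as nb
import numpy as np


@nb.njit(cache=True, fastmath=False, inline="always")
def _pair(dx, dy, dz, box, half, r2cut, s2p, e4, sh):
    """Minimum-image TSLJ pair terms: (fscal, potential, virial, within_cutoff)."""
    if dx > half:
        dx -= box
    elif dx < -half:
        dx += box
    if dy > half:
        dy -= box
    elif dy < -half:
        dy += box
    if dz > half:
        dz -= box
    elif dz < -half:
        dz += box
    r2 = dx * dx + dy * dy + dz * dz
    if r2 >= r2cut:
        return dx, dy, dz, 0.0, 0.0, 0.0, False
    s2 = s2p / r2
    s6 = s2 * s2 * s2
    s12 = s6 * s6
    pot = e4 * (s12 - s6) - sh
    fs = 6.0 * e4 * (2.0 * s12 - s6) / r2
    return dx, dy, dz, fs, pot, fs * r2, True


@nb.njit(cache=True, fastmath=False)
def forces_bruteforce(pos, box, types, eps, sig2, rc2, shift):
    """O(N^2) minimum-image pair sum. eps/sig2/rc2/shift are (ns, ns) tables."""
    n = pos.shape[0]
    half = 0.5 * box
    f = np.zeros((n, 3))
    pot = 0.0
    vir = 0.0
    for i in range(n - 1):
        ti = types[i]
        for j in range(i + 1, n):
            tj = types[j]
            dx, dy, dz, fs, u, w, ok = _pair(
                pos[i, 0] - pos[j, 0],
                pos[i, 1] - pos[j, 1],
                pos[i, 2] - pos[j, 2],
                box, half, rc2[ti, tj], sig2[ti, tj],
                4.0 * eps[ti, tj], shift[ti, tj],
            )
            if ok:
                pot += u
                vir += w
                f[i, 0] += fs * dx
                f[i, 1] += fs * dy
                f[i, 2] += fs * dz
                f[j, 0] -= fs * dx
                f[j, 1] -= fs * dy
                f[j, 2] -= fs * dz
    return f, pot, vir


@nb.njit(cache=True, fastmath=False)
def forces_cells(pos, box, types, eps, sig2, rc2, shift, ncell):
    """Cell-list pair sum over cell-sorted index arrays; requires ncell >= 3
    and box/ncell >= cutoff."""
    n = pos.shape[0]
    half = 0.5 * box
    f = np.zeros((n, 3))
    pot = 0.0
    vir = 0.0
    cw = box / ncell
    ncell3 = ncell * ncell * ncell

    # counting sort of particles into cells
    cell_of = np.empty(n, dtype=np.int64)
    count = np.zeros(ncell3 + 1, dtype=np.int64)
    for i in range(n):
        ix = int(pos[i, 0] / cw)
        iy = int(pos[i, 1] / cw)
        iz = int(pos[i, 2] / cw)
        if ix >= ncell:
            ix = ncell - 1
        if iy >= ncell:
            iy = ncell - 1
        if iz >= ncell:
            iz = ncell - 1
        c = (ix * ncell + iy) * ncell + iz
        cell_of[i] = c
        count[c + 1] += 1
    start = np.cumsum(count)
    fill = start[:-1].copy()
    order = np.empty(n, dtype=np.int64)
    for i in range(n):
        c = cell_of[i]
        order[fill[c]] = i
        fill[c] += 1

    # 13 half-space neighbor offsets
    offsets = np.empty((13, 3), dtype=np.int64)
    k = 0
    for ox in range(-1, 2):
        for oy in range(-1, 2):
            for oz in range(-1, 2):
                if oz > 0 or (oz == 0 and oy > 0) or (oz == 0 and oy == 0 and ox > 0):
                    offsets[k, 0] = ox
                    offsets[k, 1] = oy
                    offsets[k, 2] = oz
                    k += 1

    for cx in range(ncell):
        for cy in range(ncell):
            for cz in range(ncell):
                c = (cx * ncell + cy) * ncell + cz
                a0, a1 = start[c], start[c + 1]
                # pairs within the cell
                for ii in range(a0, a1 - 1):
                    i = order[ii]
                    ti = types[i]
                    for jj in range(ii + 1, a1):
                        j = order[jj]
                        tj = types[j]
                        dx, dy, dz, fs, u, w, ok = _pair(
                            pos[i, 0] - pos[j, 0],
                            pos[i, 1] - pos[j, 1],
                            pos[i, 2] - pos[j, 2],
                            box, half, rc2[ti, tj], sig2[ti, tj],
                            4.0 * eps[ti, tj], shift[ti, tj],
                        )
                        if ok:
                            pot += u
                            vir += w
                            f[i, 0] += fs * dx
                            f[i, 1] += fs * dy
                            f[i, 2] += fs * dz
                            f[j, 0] -= fs * dx
                            f[j, 1] -= fs * dy
                            f[j, 2] -= fs * dz
                # pairs with half the neighbor cells
                for m in range(13):
                    nx = (cx + offsets[m, 0]) % ncell
                    ny = (cy + offsets[m, 1]) % ncell
                    nz = (cz + offsets[m, 2]) % ncell
                    cn = (nx * ncell + ny) * ncell + nz
                    b0, b1 = start[cn], start[cn + 1]
                    for ii in range(a0, a1):
                        i = order[ii]
                        ti = types[i]
                        for jj in range(b0, b1):
                            j = order[jj]
                            tj = types[j]
                            dx, dy, dz, fs, u, w, ok = _pair(
                                pos[i, 0] - pos[j, 0],
                                pos[i, 1] - pos[j, 1],
                                pos[i, 2] - pos[j, 2],
                                box, half, rc2[ti, tj], sig2[ti, tj],
                                4.0 * eps[ti, tj], shift[ti, tj],
                            )
                            if ok:
                                pot += u
                                vir += w
                                f[i, 0] += fs * dx
                                f[i, 1] += fs * dy
                                f[i, 2] += fs * dz
                                f[j, 0] -= fs * dx
                                f[j, 1] -= fs * dy
                                f[j, 2] -= fs * dz
    return f, pot, vir
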