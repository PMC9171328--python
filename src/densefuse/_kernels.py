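"""Numba kernels for patch matching, label-vote accumulation and NLM.

Conventions shared by every kernel here:

* intensity grids are passed edge-padded by the patch half-width ``hw``, so
  the patch centred on voxel ``i`` spans padded indices ``[i, i + p)``;
* search windows are expressed in *unpadded* voxel coordinates and clamped
  to the grid;
* patch distance is the squared L2 norm divided by the number of patch
  elements (a mean of squared differences);
* candidate lists are kept sorted ascending by distance, best first.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True, inline="always")
def _patch_dist(subpad, libpad, s, ix, iy, iz, jx, jy, jz, p):
    d = 0.0
    for a in range(p):
        for b in range(p):
            for c in range(p):
                diff = subpad[ix + a, iy + b, iz + c] - libpad[s, jx + a, jy + b, jz + c]
                d += diff * diff
    return d / (p * p * p)


@njit(cache=True)
def exhaustive_fuse_kernel(
    subpad, libpad, labstack, positions, lut, n_labels, shape, p, radius, h_eps
):
    """Brute-force non-local label fusion with central-voxel voting.

    For each masked voxel every window position of every library member
    contributes ``exp(-D / h^2)`` to the label at that position, with
    ``h^2 = min(D) + h_eps`` taken over the voxel's whole search volume.
    Returns per-voxel probability rows (M, n_labels), normalised.
    """
    nmem = libpad.shape[0]
    nx, ny, nz = shape
    m_total = positions.shape[0]
    probs = np.zeros((m_total, n_labels), dtype=np.float64)
    for m in range(m_total):
        ix, iy, iz = positions[m, 0], positions[m, 1], positions[m, 2]
        x0, x1 = max(0, ix - radius), min(nx - 1, ix + radius)
        y0, y1 = max(0, iy - radius), min(ny - 1, iy + radius)
        z0, z1 = max(0, iz - radius), min(nz - 1, iz + radius)
        dmin = np.inf
        for s in range(nmem):
            for jx in range(x0, x1 + 1):
                for jy in range(y0, y1 + 1):
                    for jz in range(z0, z1 + 1):
                        d = _patch_dist(subpad, libpad, s, ix, iy, iz, jx, jy, jz, p)
                        if d < dmin:
                            dmin = d
        h2 = dmin + h_eps
        total = 0.0
        for s in range(nmem):
            for jx in range(x0, x1 + 1):
                for jy in range(y0, y1 + 1):
                    for jz in range(z0, z1 + 1):
                        d = _patch_dist(subpad, libpad, s, ix, iy, iz, jx, jy, jz, p)
                        w = np.exp(-d / h2)
                        lab = labstack[s, jx, jy, jz]
                        probs[m, lut[lab]] += w
                        total += w
        for l in range(n_labels):
            probs[m, l] /= total
    return probs


@njit(cache=True, inline="always")
def _try_insert(cand_s, cand_x, cand_y, cand_z, cand_d, cand_n, m, k, s, jx, jy, jz, d):
    """Insert candidate (s, j, d) into voxel m's sorted list; skip duplicates.

    Returns the updated candidate count for voxel m.
    """
    n = cand_n[m]
    for c in range(n):
        if cand_s[m, c] == s and cand_x[m, c] == jx and cand_y[m, c] == jy and cand_z[m, c] == jz:
            return n
    if n < k:
        pos = n
        n += 1
    elif d < cand_d[m, k - 1]:
        pos = k - 1
    else:
        return n
    # shift worse entries down, keep ascending order
    while pos > 0 and cand_d[m, pos - 1] > d:
        cand_s[m, pos] = cand_s[m, pos - 1]
        cand_x[m, pos] = cand_x[m, pos - 1]
        cand_y[m, pos] = cand_y[m, pos - 1]
        cand_z[m, pos] = cand_z[m, pos - 1]
        cand_d[m, pos] = cand_d[m, pos - 1]
        pos -= 1
    cand_s[m, pos] = s
    cand_x[m, pos] = jx
    cand_y[m, pos] = jy
    cand_z[m, pos] = jz
    cand_d[m, pos] = d
    return n


@njit(cache=True)
def enumerate_field_kernel(subpad, libpad, positions, shape, p, radius, k):
    """Exhaustive best-k field: every window position of every member scored."""
    nmem = libpad.shape[0]
    nx, ny, nz = shape
    m_total = positions.shape[0]
    cand_s = np.full((m_total, k), -1, dtype=np.int32)
    cand_x = np.zeros((m_total, k), dtype=np.int32)
    cand_y = np.zeros((m_total, k), dtype=np.int32)
    cand_z = np.zeros((m_total, k), dtype=np.int32)
    cand_d = np.full((m_total, k), np.inf, dtype=np.float64)
    cand_n = np.zeros(m_total, dtype=np.int32)
    for m in range(m_total):
        ix, iy, iz = positions[m, 0], positions[m, 1], positions[m, 2]
        x0, x1 = max(0, ix - radius), min(nx - 1, ix + radius)
        y0, y1 = max(0, iy - radius), min(ny - 1, iy + radius)
        z0, z1 = max(0, iz - radius), min(nz - 1, iz + radius)
        for s in range(nmem):
            for jx in range(x0, x1 + 1):
                for jy in range(y0, y1 + 1):
                    for jz in range(z0, z1 + 1):
                        d = _patch_dist(subpad, libpad, s, ix, iy, iz, jx, jy, jz, p)
                        cand_n[m] = _try_insert(
                            cand_s, cand_x, cand_y, cand_z, cand_d, cand_n,
                            m, k, s, jx, jy, jz, d,
                        )
    return cand_s, cand_x, cand_y, cand_z, cand_d, cand_n


@njit(cache=True)
def patchmatch_kernel(
    subpad, libpad, positions, idx_map, shape, p, radius, k, iters, seed
):
    """Randomised approximate nearest-neighbour field (PatchMatch lineage).

    Random initialisation of up to k candidates per masked voxel, then
    ``iters`` rounds of scan-order propagation from already-visited spatial
    neighbours followed by constrained random search with a geometrically
    decaying radius. Candidate lists only ever improve, so the mean best
    distance is non-increasing across iterations (returned for inspection).
    """
    np.random.seed(seed)
    nmem = libpad.shape[0]
    nx, ny, nz = shape
    m_total = positions.shape[0]
    cand_s = np.full((m_total, k), -1, dtype=np.int32)
    cand_x = np.zeros((m_total, k), dtype=np.int32)
    cand_y = np.zeros((m_total, k), dtype=np.int32)
    cand_z = np.zeros((m_total, k), dtype=np.int32)
    cand_d = np.full((m_total, k), np.inf, dtype=np.float64)
    cand_n = np.zeros(m_total, dtype=np.int32)

    # --- random initialisation -------------------------------------------
    for m in range(m_total):
        ix, iy, iz = positions[m, 0], positions[m, 1], positions[m, 2]
        x0, x1 = max(0, ix - radius), min(nx - 1, ix + radius)
        y0, y1 = max(0, iy - radius), min(ny - 1, iy + radius)
        z0, z1 = max(0, iz - radius), min(nz - 1, iz + radius)
        pool = (x1 - x0 + 1) * (y1 - y0 + 1) * (z1 - z0 + 1) * nmem
        want = min(k, pool)
        attempts = 0
        while cand_n[m] < want and attempts < 16 * k:
            s = np.random.randint(0, nmem)
            jx = np.random.randint(x0, x1 + 1)
            jy = np.random.randint(y0, y1 + 1)
            jz = np.random.randint(z0, z1 + 1)
            d = _patch_dist(subpad, libpad, s, ix, iy, iz, jx, jy, jz, p)
            cand_n[m] = _try_insert(
                cand_s, cand_x, cand_y, cand_z, cand_d, cand_n, m, k, s, jx, jy, jz, d
            )
            attempts += 1

    mean_best = np.zeros(iters + 1, dtype=np.float64)
    acc = 0.0
    for m in range(m_total):
        acc += cand_d[m, 0]
    mean_best[0] = acc / m_total

    # --- iterations: propagation + random search -------------------------
    for it in range(iters):
        forward = it % 2 == 0
        for step in range(m_total):
            m = step if forward else m_total - 1 - step
            ix, iy, iz = positions[m, 0], positions[m, 1], positions[m, 2]
            x0, x1 = max(0, ix - radius), min(nx - 1, ix + radius)
            y0, y1 = max(0, iy - radius), min(ny - 1, iy + radius)
            z0, z1 = max(0, iz - radius), min(nz - 1, iz + radius)
            sign = 1 if forward else -1
            # propagation from the three already-scanned spatial neighbours
            for axis in range(3):
                px, py, pz = ix, iy, iz
                if axis == 0:
                    px -= sign
                elif axis == 1:
                    py -= sign
                else:
                    pz -= sign
                if px < 0 or px >= nx or py < 0 or py >= ny or pz < 0 or pz >= nz:
                    continue
                nb = idx_map[px, py, pz]
                if nb < 0:
                    continue
                for c in range(cand_n[nb]):
                    s = cand_s[nb, c]
                    jx = cand_x[nb, c]
                    jy = cand_y[nb, c]
                    jz = cand_z[nb, c]
                    if axis == 0:
                        jx += sign
                    elif axis == 1:
                        jy += sign
                    else:
                        jz += sign
                    if jx < x0 or jx > x1 or jy < y0 or jy > y1 or jz < z0 or jz > z1:
                        continue
                    d = _patch_dist(subpad, libpad, s, ix, iy, iz, jx, jy, jz, p)
                    cand_n[m] = _try_insert(
                        cand_s, cand_x, cand_y, cand_z, cand_d, cand_n,
                        m, k, s, jx, jy, jz, d,
                    )
            # constrained random search around the current best, radius halving
            bx = cand_x[m, 0] if cand_n[m] > 0 else ix
            by = cand_y[m, 0] if cand_n[m] > 0 else iy
            bz = cand_z[m, 0] if cand_n[m] > 0 else iz
            w = radius
            while w >= 1:
                s = np.random.randint(0, nmem)
                jx = bx + np.random.randint(-w, w + 1)
                jy = by + np.random.randint(-w, w + 1)
                jz = bz + np.random.randint(-w, w + 1)
                if x0 <= jx <= x1 and y0 <= jy <= y1 and z0 <= jz <= z1:
                    d = _patch_dist(subpad, libpad, s, ix, iy, iz, jx, jy, jz, p)
                    cand_n[m] = _try_insert(
                        cand_s, cand_x, cand_y, cand_z, cand_d, cand_n,
                        m, k, s, jx, jy, jz, d,
                    )
                w //= 2
        acc = 0.0
        for m in range(m_total):
            acc += cand_d[m, 0]
        mean_best[it + 1] = acc / m_total

    return cand_s, cand_x, cand_y, cand_z, cand_d, cand_n, mean_best


@njit(cache=True)
def vote_center_kernel(
    labstack, positions, cand_s, cand_x, cand_y, cand_z, cand_d, cand_n,
    lut, n_labels, h_eps,
):
    """Central-voxel voting: each candidate votes only the label at its centre."""
    m_total = positions.shape[0]
    probs = np.zeros((m_total, n_labels), dtype=np.float64)
    for m in range(m_total):
        n = cand_n[m]
        if n == 0:
            continue
        h2 = cand_d[m, 0] + h_eps
        total = 0.0
        for c in range(n):
            w = np.exp(-cand_d[m, c] / h2)
            lab = labstack[cand_s[m, c], cand_x[m, c], cand_y[m, c], cand_z[m, c]]
            probs[m, lut[lab]] += w
            total += w
        for l in range(n_labels):
            probs[m, l] /= total
    return probs


@njit(cache=True)
def vote_patchwise_kernel(
    labpad, positions, cand_s, cand_x, cand_y, cand_z, cand_d, cand_n,
    lut, n_labels, shape, p, hw, h_eps,
):
    """Patchwise late aggregation: each matched patch votes labels for every
    voxel it covers, with the weight computed at its centre.

    Accumulates over the full grid; the caller masks and normalises."""
    nx, ny, nz = shape
    m_total = positions.shape[0]
    acc = np.zeros((n_labels, nx, ny, nz), dtype=np.float64)
    wsum = np.zeros((nx, ny, nz), dtype=np.float64)
    for m in range(m_total):
        n = cand_n[m]
        if n == 0:
            continue
        ix, iy, iz = positions[m, 0], positions[m, 1], positions[m, 2]
        h2 = cand_d[m, 0] + h_eps
        for c in range(n):
            w = np.exp(-cand_d[m, c] / h2)
            s = cand_s[m, c]
            jx, jy, jz = cand_x[m, c], cand_y[m, c], cand_z[m, c]
            for a in range(p):
                tx = ix + a - hw
                if tx < 0 or tx >= nx:
                    continue
                for b in range(p):
                    ty = iy + b - hw
                    if ty < 0 or ty >= ny:
                        continue
                    for cc in range(p):
                        tz = iz + cc - hw
                        if tz < 0 or tz >= nz:
                            continue
                        lab = labpad[s, jx + a, jy + b, jz + cc]
                        acc[lut[lab], tx, ty, tz] += w
                        wsum[tx, ty, tz] += w
    return acc, wsum


@njit(cache=True)
def nlm_kernel(grid, p, radius, strength, h_eps):
    """Non-local means of a scalar grid using min-distance normalised weights.

    The centre voxel gets weight 1; h^2 is ``strength * (min non-central
    distance + h_eps)`` per voxel, mirroring the patch-weight rule used for
    label fusion. Output values are convex combinations of input values.
    """
    nx, ny, nz = grid.shape
    hw = p // 2
    padded = np.empty((nx + 2 * hw, ny + 2 * hw, nz + 2 * hw), dtype=np.float64)
    for x in range(nx + 2 * hw):
        sx = min(max(x - hw, 0), nx - 1)
        for y in range(ny + 2 * hw):
            sy = min(max(y - hw, 0), ny - 1)
            for z in range(nz + 2 * hw):
                sz = min(max(z - hw, 0), nz - 1)
                padded[x, y, z] = grid[sx, sy, sz]
    out = np.empty_like(grid)
    for ix in range(nx):
        x0, x1 = max(0, ix - radius), min(nx - 1, ix + radius)
        for iy in range(ny):
            y0, y1 = max(0, iy - radius), min(ny - 1, iy + radius)
            for iz in range(nz):
                z0, z1 = max(0, iz - radius), min(nz - 1, iz + radius)
                dmin = np.inf
                for jx in range(x0, x1 + 1):
                    for jy in range(y0, y1 + 1):
                        for jz in range(z0, z1 + 1):
                            if jx == ix and jy == iy and jz == iz:
                                continue
                            d = 0.0
                            for a in range(p):
                                for b in range(p):
                                    for c in range(p):
                                        diff = (
                                            padded[ix + a, iy + b, iz + c]
                                            - padded[jx + a, jy + b, jz + c]
                                        )
                                        d += diff * diff
                            d /= p * p * p
                            if d < dmin:
                                dmin = d
                h2 = strength * (dmin + h_eps)
                wsum = 1.0
                vsum = grid[ix, iy, iz]
                for jx in range(x0, x1 + 1):
                    for jy in range(y0, y1 + 1):
                        for jz in range(z0, z1 + 1):
                            if jx == ix and jy == iy and jz == iz:
                                continue
                            d = 0.0
                            for a in range(p):
                                for b in range(p):
                                    for c in range(p):
                                        diff = (
                                            padded[ix + a, iy + b, iz + c]
                                            - padded[jx + a, jy + b, jz + c]
                                        )
                                        d += diff * diff
                            d /= p * p * p
                            w = np.exp(-d / h2)
                            wsum += w
                            vsum += w * grid[jx, jy, jz]
                out[ix, iy, iz] = vsum / wsum
    return out
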