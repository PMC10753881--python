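"""Numba kernels for the Kern-Frenkel Monte Carlo engine.

All kernels operate on flat numpy arrays; the object layer lives in
``mcsim``.  Particle state: positions (N, 3), lab-frame patch vectors
(N, Np, 3), unit quaternions (N, 4), species labels (N,).  Mixture state:
per-species patch colors (Ns, Np) and the boolean color-compatibility
matrix.  Boxes are cubic and periodic.

Randomness comes from numba's internal np.random state, seeded once per
run through ``seed_kernel_rng`` -- runs with equal seeds are bit-reproducible.

Energy convention: a configuration's energy is -eps times the number of
bonded pairs; at most one bond is counted per pair (the most aligned
compatible patch pair).  For the narrow patches used here (cos theta_max =
0.98) a single patch geometrically cannot bond two partners at once, so
pairwise counting also enforces the one-bond-per-patch rule; the bond-graph
builder in ``mcsim`` asserts it.
"""

from __future__ import annotations

import numpy as np
from numba import njit

BIG = 1.0e12  # hard-core overlap sentinel inside kernels


@njit(cache=True)
def seed_kernel_rng(seed):
    np.random.seed(seed)


@njit(cache=True, inline="always", fastmath=True)
def pair_interaction(pos, patch, species, colors, compat, box,
                     sigma, delta, cosmax, i, j):
    """Return (code, a, g): code 2 = overlap, 1 = bond via patches (a, g),
    0 = no interaction."""
    half = 0.5 * box
    dx = pos[j, 0] - pos[i, 0]
    if dx > half:
        dx -= box
    elif dx < -half:
        dx += box
    dy = pos[j, 1] - pos[i, 1]
    if dy > half:
        dy -= box
    elif dy < -half:
        dy += box
    dz = pos[j, 2] - pos[i, 2]
    if dz > half:
        dz -= box
    elif dz < -half:
        dz += box
    r2 = dx * dx + dy * dy + dz * dz
    rc = sigma * (1.0 + delta)
    if r2 >= rc * rc:
        return 0, -1, -1
    if r2 < sigma * sigma:
        return 2, -1, -1
    r = np.sqrt(r2)
    ux, uy, uz = dx / r, dy / r, dz / r
    si = species[i]
    sj = species[j]
    npatch = patch.shape[1]
    best_a = -1
    best_g = -1
    best_s = -1.0e30
    for a in range(npatch):
        ca = patch[i, a, 0] * ux + patch[i, a, 1] * uy + patch[i, a, 2] * uz
        if ca < cosmax:
            continue
        for g in range(npatch):
            cg = -(patch[j, g, 0] * ux + patch[j, g, 1] * uy + patch[j, g, 2] * uz)
            if cg < cosmax:
                continue
            if compat[colors[si, a], colors[sj, g]] == 0:
                continue
            s = ca + cg
            if s > best_s:
                best_s = s
                best_a = a
                best_g = g
    if best_a >= 0:
        return 1, best_a, best_g
    return 0, -1, -1


@njit(cache=True, fastmath=True)
def particle_energy(pos, patch, species, colors, compat, box,
                    sigma, delta, cosmax, eps, idx, n, i):
    """Energy of particle i against the n particles listed in idx (skips i).

    Positions may lie slightly outside [0, box); displacements are reduced
    by at most one box image, which is exact as long as particles never
    stray more than one box length (the move kernels re-wrap on every
    accepted move).
    """
    e = 0.0
    rc = sigma * (1.0 + delta)
    rc2 = rc * rc
    s2 = sigma * sigma
    half = 0.5 * box
    xi, yi, zi = pos[i, 0], pos[i, 1], pos[i, 2]
    npatch = patch.shape[1]
    si = species[i]
    for k in range(n):
        j = idx[k]
        if j == i:
            continue
        dx = pos[j, 0] - xi
        if dx > half:
            dx -= box
        elif dx < -half:
            dx += box
        if dx > rc or dx < -rc:
            continue
        dy = pos[j, 1] - yi
        if dy > half:
            dy -= box
        elif dy < -half:
            dy += box
        if dy > rc or dy < -rc:
            continue
        dz = pos[j, 2] - zi
        if dz > half:
            dz -= box
        elif dz < -half:
            dz += box
        r2 = dx * dx + dy * dy + dz * dz
        if r2 >= rc2:
            continue
        if r2 < s2:
            return BIG
        r = np.sqrt(r2)
        ux, uy, uz = dx / r, dy / r, dz / r
        sj = species[j]
        bonded = False
        for a in range(npatch):
            ca = patch[i, a, 0] * ux + patch[i, a, 1] * uy + patch[i, a, 2] * uz
            if ca < cosmax:
                continue
            for g in range(npatch):
                cg = -(patch[j, g, 0] * ux + patch[j, g, 1] * uy + patch[j, g, 2] * uz)
                if cg < cosmax:
                    continue
                if compat[colors[si, a], colors[sj, g]] != 0:
                    bonded = True
                    break
            if bonded:
                break
        if bonded:
            e -= eps
    return e


@njit(cache=True, fastmath=True)
def total_energy_kernel(pos, patch, species, colors, compat, box,
                        sigma, delta, cosmax, eps, idx, n):
    e = 0.0
    for a in range(n - 1):
        i = idx[a]
        for b in range(a + 1, n):
            j = idx[b]
            code, _, _ = pair_interaction(pos, patch, species, colors, compat, box,
                                          sigma, delta, cosmax, i, j)
            if code == 2:
                return BIG
            if code == 1:
                e -= eps
    return e


@njit(cache=True)
def bond_list_kernel(pos, patch, species, colors, compat, box,
                     sigma, delta, cosmax, idx, n, out_edges):
    """Fill out_edges (max_edges, 4) with (i, a, j, g); return count (or -1
    on overlap)."""
    m = 0
    for a_ in range(n - 1):
        i = idx[a_]
        for b_ in range(a_ + 1, n):
            j = idx[b_]
            code, a, g = pair_interaction(pos, patch, species, colors, compat, box,
                                          sigma, delta, cosmax, i, j)
            if code == 2:
                return -1
            if code == 1:
                out_edges[m, 0] = i
                out_edges[m, 1] = a
                out_edges[m, 2] = j
                out_edges[m, 3] = g
                m += 1
    return m


@njit(cache=True, inline="always")
def _rotate_patches_small(patch, i, ax, ay, az, angle):
    """Rotate particle i's patch vectors about unit axis by angle (Rodrigues)."""
    c = np.cos(angle)
    s = np.sin(angle)
    for a in range(patch.shape[1]):
        vx, vy, vz = patch[i, a, 0], patch[i, a, 1], patch[i, a, 2]
        dot = ax * vx + ay * vy + az * vz
        cx = ay * vz - az * vy
        cy = az * vx - ax * vz
        cz = ax * vy - ay * vx
        patch[i, a, 0] = vx * c + cx * s + ax * dot * (1 - c)
        patch[i, a, 1] = vy * c + cy * s + ay * dot * (1 - c)
        patch[i, a, 2] = vz * c + cz * s + az * dot * (1 - c)


@njit(cache=True, inline="always")
def _quat_mul_into(q, i, w2, x2, y2, z2):
    w1, x1, y1, z1 = q[i, 0], q[i, 1], q[i, 2], q[i, 3]
    q[i, 0] = w2 * w1 - x2 * x1 - y2 * y1 - z2 * z1
    q[i, 1] = w2 * x1 + x2 * w1 + y2 * z1 - z2 * y1
    q[i, 2] = w2 * y1 - x2 * z1 + y2 * w1 + z2 * x1
    q[i, 3] = w2 * z1 + x2 * y1 - y2 * x1 + z2 * w1
    norm = np.sqrt(q[i, 0] ** 2 + q[i, 1] ** 2 + q[i, 2] ** 2 + q[i, 3] ** 2)
    for k in range(4):
        q[i, k] /= norm


@njit(cache=True)
def _set_orientation(patch, quat, body_patches, species, i, w, x, y, z):
    """Set particle i's quaternion and recompute its lab patches."""
    norm = np.sqrt(w * w + x * x + y * y + z * z)
    w, x, y, z = w / norm, x / norm, y / norm, z / norm
    quat[i, 0], quat[i, 1], quat[i, 2], quat[i, 3] = w, x, y, z
    r00 = 1 - 2 * (y * y + z * z)
    r01 = 2 * (x * y - w * z)
    r02 = 2 * (x * z + w * y)
    r10 = 2 * (x * y + w * z)
    r11 = 1 - 2 * (x * x + z * z)
    r12 = 2 * (y * z - w * x)
    r20 = 2 * (x * z - w * y)
    r21 = 2 * (y * z + w * x)
    r22 = 1 - 2 * (x * x + y * y)
    s = species[i]
    for a in range(patch.shape[1]):
        bx, by, bz = body_patches[s, a, 0], body_patches[s, a, 1], body_patches[s, a, 2]
        patch[i, a, 0] = r00 * bx + r01 * by + r02 * bz
        patch[i, a, 1] = r10 * bx + r11 * by + r12 * bz
        patch[i, a, 2] = r20 * bx + r21 * by + r22 * bz


@njit(cache=True)
def _random_unit_vector():
    while True:
        x = 2.0 * np.random.random() - 1.0
        y = 2.0 * np.random.random() - 1.0
        z = 2.0 * np.random.random() - 1.0
        r2 = x * x + y * y + z * z
        if 1e-8 < r2 <= 1.0:
            r = np.sqrt(r2)
            return x / r, y / r, z / r


@njit(cache=True)
def _random_quat():
    u1 = np.random.random()
    u2 = np.random.random()
    u3 = np.random.random()
    a = np.sqrt(1.0 - u1)
    b = np.sqrt(u1)
    return (a * np.sin(2 * np.pi * u2), a * np.cos(2 * np.pi * u2),
            b * np.sin(2 * np.pi * u3), b * np.cos(2 * np.pi * u3))


@njit(cache=True)
def _cone_vector(ax, ay, az, cosmax):
    """Uniform unit vector in the spherical cap around axis (cos >= cosmax)."""
    c = cosmax + (1.0 - cosmax) * np.random.random()
    s = np.sqrt(max(0.0, 1.0 - c * c))
    phi = 2.0 * np.pi * np.random.random()
    # orthonormal frame around the axis
    if abs(ax) < 0.9:
        bx, by, bz = 1.0, 0.0, 0.0
    else:
        bx, by, bz = 0.0, 1.0, 0.0
    e1x = ay * bz - az * by
    e1y = az * bx - ax * bz
    e1z = ax * by - ay * bx
    n1 = np.sqrt(e1x * e1x + e1y * e1y + e1z * e1z)
    e1x, e1y, e1z = e1x / n1, e1y / n1, e1z / n1
    e2x = ay * e1z - az * e1y
    e2y = az * e1x - ax * e1z
    e2z = ax * e1y - ay * e1x
    cp = np.cos(phi)
    sp = np.sin(phi)
    return (c * ax + s * (cp * e1x + sp * e2x),
            c * ay + s * (cp * e1y + sp * e2y),
            c * az + s * (cp * e1z + sp * e2z))


@njit(cache=True)
def _orientation_with_patch_along(patch, quat, body_patches, species, j, g,
                                  dx, dy, dz, cosmax):
    """Give particle j a random orientation whose body patch g points into
    the cone around (dx, dy, dz): uniform over the constrained manifold."""
    tx, ty, tz = _cone_vector(dx, dy, dz, cosmax)
    s = species[j]
    bx, by, bz = body_patches[s, g, 0], body_patches[s, g, 1], body_patches[s, g, 2]
    # quaternion rotating b onto t, then random spin about t
    cx = by * tz - bz * ty
    cy = bz * tx - bx * tz
    cz = bx * ty - by * tx
    d = bx * tx + by * ty + bz * tz
    if d < -1.0 + 1e-12:
        # opposite: rotate pi about any axis perpendicular to b
        if abs(bx) < 0.9:
            px, py, pz = 1.0, 0.0, 0.0
        else:
            px, py, pz = 0.0, 1.0, 0.0
        axx = by * pz - bz * py
        axy = bz * px - bx * pz
        axz = bx * py - by * px
        n = np.sqrt(axx * axx + axy * axy + axz * axz)
        qw, qx, qy, qz = 0.0, axx / n, axy / n, axz / n
    else:
        qw = 1.0 + d
        qx, qy, qz = cx, cy, cz
        n = np.sqrt(qw * qw + qx * qx + qy * qy + qz * qz)
        qw, qx, qy, qz = qw / n, qx / n, qy / n, qz / n
    psi = 2.0 * np.pi * np.random.random()
    hw = np.cos(0.5 * psi)
    hs = np.sin(0.5 * psi)
    sw, sx, sy, sz = hw, hs * tx, hs * ty, hs * tz
    # total = spin * align
    w = sw * qw - sx * qx - sy * qy - sz * qz
    x = sw * qx + sx * qw + sy * qz - sz * qy
    y = sw * qy - sx * qz + sy * qw + sz * qx
    z = sw * qz + sx * qy - sy * qx + sz * qw
    _set_orientation(patch, quat, body_patches, species, j, w, x, y, z)


@njit(cache=True)
def _bonded_partners(pos, patch, species, colors, compat, box,
                     sigma, delta, cosmax, idx, n, i, partners, bonded_patch):
    """Partners of i among idx; fills partners (ids) and bonded_patch[a] = 1
    for each bonded patch a of i.  Returns the number of partners."""
    for a in range(bonded_patch.shape[0]):
        bonded_patch[a] = 0
    m = 0
    for k in range(n):
        j = idx[k]
        if j == i:
            continue
        code, a, g = pair_interaction(pos, patch, species, colors, compat, box,
                                      sigma, delta, cosmax, i, j)
        if code == 1:
            partners[m] = j
            bonded_patch[a] = 1
            m += 1
    return m


@njit(cache=True)
def _free_pair_count(patch_free, colors, compat, si, sj, npatch):
    """Count compatible (a on i, g on j) pairs with a free on i."""
    n = 0
    for a in range(npatch):
        if patch_free[a] == 0:
            continue
        for g in range(npatch):
            if compat[colors[si, a], colors[sj, g]] != 0:
                n += 1
    return n


@njit(cache=True, fastmath=True)
def _run_moves(pos, patch, quat, species, colors, compat, body_patches, box,
               sigma, delta, cosmax, eps, beta, idx, n,
               dmax, rotmax, p_roto, p_avbb, vb,
               n_moves, counters):
    """Run n_moves trial moves on the particles listed in idx.  Returns the
    total energy change.  counters: (roto_acc, roto_try, avbb_acc, avbb_try,
    avbu_acc, avbu_try) accumulated in place."""
    de_total = 0.0
    npatch = patch.shape[1]
    partners = np.empty(n, dtype=np.int64)
    patch_bonded = np.empty(npatch, dtype=np.int64)
    patch_free = np.empty(npatch, dtype=np.int64)
    old_pos = np.empty(3)
    old_patch = np.empty((npatch, 3))
    old_quat = np.empty(4)
    vol = box * box * box
    if True:
        for _m in range(n_moves):
            u = np.random.random()
            i = idx[int(np.random.random() * n)]
            if u < p_roto:
                counters[1] += 1
                e_old = particle_energy(pos, patch, species, colors, compat, box,
                                        sigma, delta, cosmax, eps, idx, n, i)
                for d in range(3):
                    old_pos[d] = pos[i, d]
                for a in range(npatch):
                    for d in range(3):
                        old_patch[a, d] = patch[i, a, d]
                for d in range(4):
                    old_quat[d] = quat[i, d]
                for d in range(3):
                    pos[i, d] += dmax * (2.0 * np.random.random() - 1.0)
                    if pos[i, d] >= box:
                        pos[i, d] -= box
                    elif pos[i, d] < 0.0:
                        pos[i, d] += box
                ax, ay, az = _random_unit_vector()
                angle = rotmax * (2.0 * np.random.random() - 1.0)
                _rotate_patches_small(patch, i, ax, ay, az, angle)
                half = 0.5 * angle
                _quat_mul_into(quat, i, np.cos(half), np.sin(half) * ax,
                               np.sin(half) * ay, np.sin(half) * az)
                e_new = particle_energy(pos, patch, species, colors, compat, box,
                                        sigma, delta, cosmax, eps, idx, n, i)
                de = e_new - e_old
                if e_new >= BIG or (de > 0 and np.random.random() >= np.exp(-beta * de)):
                    for d in range(3):
                        pos[i, d] = old_pos[d]
                    for a in range(npatch):
                        for d in range(3):
                            patch[i, a, d] = old_patch[a, d]
                    for d in range(4):
                        quat[i, d] = old_quat[d]
                else:
                    counters[0] += 1
                    de_total += de
            elif u < p_roto + p_avbb:
                # AVB-B: bond a non-partner j to a free compatible patch of i
                counters[3] += 1
                if n < 2:
                    continue
                n_in = _bonded_partners(pos, patch, species, colors, compat, box,
                                        sigma, delta, cosmax, idx, n, i,
                                        partners, patch_bonded)
                n_out = n - 1 - n_in
                if n_out <= 0:
                    continue
                # pick j uniformly among non-partners
                pick = int(np.random.random() * n_out)
                j = -1
                cnt = 0
                for k in range(n):
                    cand = idx[k]
                    if cand == i:
                        continue
                    isb = False
                    for q_ in range(n_in):
                        if partners[q_] == cand:
                            isb = True
                            break
                    if isb:
                        continue
                    if cnt == pick:
                        j = cand
                        break
                    cnt += 1
                if j < 0:
                    continue
                for a in range(npatch):
                    patch_free[a] = 1 - patch_bonded[a]
                n_pairs = _free_pair_count(patch_free, colors, compat,
                                           species[i], species[j], npatch)
                if n_pairs == 0:
                    continue
                # choose the (a, g) pair uniformly
                pick = int(np.random.random() * n_pairs)
                sel_a = -1
                sel_g = -1
                cnt = 0
                for a in range(npatch):
                    if patch_free[a] == 0:
                        continue
                    for g in range(npatch):
                        if compat[colors[species[i], a], colors[species[j], g]] != 0:
                            if cnt == pick:
                                sel_a = a
                                sel_g = g
                            cnt += 1
                e_old = particle_energy(pos, patch, species, colors, compat, box,
                                        sigma, delta, cosmax, eps, idx, n, j)
                for d in range(3):
                    old_pos[d] = pos[j, d]
                for a in range(npatch):
                    for d in range(3):
                        old_patch[a, d] = patch[j, a, d]
                for d in range(4):
                    old_quat[d] = quat[j, d]
                # sample r-hat in the cone of patch sel_a, r uniform in shell
                hx, hy, hz = _cone_vector(patch[i, sel_a, 0], patch[i, sel_a, 1],
                                          patch[i, sel_a, 2], cosmax)
                rc = sigma * (1.0 + delta)
                r3 = sigma ** 3 + np.random.random() * (rc ** 3 - sigma ** 3)
                r = r3 ** (1.0 / 3.0)
                pos[j, 0] = pos[i, 0] + r * hx
                pos[j, 1] = pos[i, 1] + r * hy
                pos[j, 2] = pos[i, 2] + r * hz
                for d in range(3):
                    if pos[j, d] >= box:
                        pos[j, d] -= box
                    elif pos[j, d] < 0.0:
                        pos[j, d] += box
                _orientation_with_patch_along(patch, quat, body_patches, species,
                                              j, sel_g, -hx, -hy, -hz, cosmax)
                e_new = particle_energy(pos, patch, species, colors, compat, box,
                                        sigma, delta, cosmax, eps, idx, n, j)
                acc = 0.0
                if e_new < BIG:
                    de = e_new - e_old
                    v_in = n_pairs * vb
                    v_out = vol - v_in
                    ratio = np.exp(-beta * de) * (n_out / (n_in + 1.0)) * (v_in / v_out)
                    acc = min(1.0, ratio)
                if np.random.random() < acc:
                    counters[2] += 1
                    de_total += e_new - e_old
                else:
                    for d in range(3):
                        pos[j, d] = old_pos[d]
                    for a in range(npatch):
                        for d in range(3):
                            patch[j, a, d] = old_patch[a, d]
                    for d in range(4):
                        quat[j, d] = old_quat[d]
            else:
                # AVB-U: unbind a partner j of i to a uniform non-bonded pose
                counters[5] += 1
                n_in = _bonded_partners(pos, patch, species, colors, compat, box,
                                        sigma, delta, cosmax, idx, n, i,
                                        partners, patch_bonded)
                if n_in == 0:
                    continue
                j = partners[int(np.random.random() * n_in)]
                # free-pair count discounting the i-j bond itself
                code, a_ij, _g = pair_interaction(pos, patch, species, colors,
                                                  compat, box, sigma, delta,
                                                  cosmax, i, j)
                for a in range(npatch):
                    patch_free[a] = 1 - patch_bonded[a]
                if code == 1:
                    patch_free[a_ij] = 1
                n_pairs = _free_pair_count(patch_free, colors, compat,
                                           species[i], species[j], npatch)
                if n_pairs == 0:
                    continue
                e_old = particle_energy(pos, patch, species, colors, compat, box,
                                        sigma, delta, cosmax, eps, idx, n, j)
                for d in range(3):
                    old_pos[d] = pos[j, d]
                for a in range(npatch):
                    for d in range(3):
                        old_patch[a, d] = patch[j, a, d]
                for d in range(4):
                    old_quat[d] = quat[j, d]
                pos[j, 0] = box * np.random.random()
                pos[j, 1] = box * np.random.random()
                pos[j, 2] = box * np.random.random()
                qw, qx, qy, qz = _random_quat()
                _set_orientation(patch, quat, body_patches, species, j, qw, qx, qy, qz)
                code2, _a2, _g2 = pair_interaction(pos, patch, species, colors,
                                                   compat, box, sigma, delta,
                                                   cosmax, i, j)
                acc = 0.0
                if code2 == 0:  # must land outside i's bonding region
                    e_new = particle_energy(pos, patch, species, colors, compat, box,
                                            sigma, delta, cosmax, eps, idx, n, j)
                    if e_new < BIG:
                        de = e_new - e_old
                        v_in = n_pairs * vb
                        v_out = vol - v_in
                        ratio = (np.exp(-beta * de) * (n_in / (n - n_in))
                                 * (v_out / v_in))
                        acc = min(1.0, ratio)
                        if np.random.random() < acc:
                            counters[4] += 1
                            de_total += e_new - e_old
                            continue
                for d in range(3):
                    pos[j, d] = old_pos[d]
                for a in range(npatch):
                    for d in range(3):
                        patch[j, a, d] = old_patch[a, d]
                for d in range(4):
                    quat[j, d] = old_quat[d]
    return de_total


@njit(cache=True, fastmath=True)
def sweep_nvt(pos, patch, quat, species, colors, compat, body_patches, box,
              sigma, delta, cosmax, eps, beta, idx, n,
              dmax, rotmax, p_roto, p_avbb, vb,
              n_sweeps, counters):
    """n_sweeps sweeps of n trial moves each; returns the total energy change."""
    de = 0.0
    for _ in range(n_sweeps):
        de += _run_moves(pos, patch, quat, species, colors, compat, body_patches,
                         box, sigma, delta, cosmax, eps, beta, idx, n,
                         dmax, rotmax, p_roto, p_avbb, vb, n, counters)
    return de


@njit(cache=True, fastmath=True)
def sweep_gibbs(pos, patch, quat, species, colors, compat, body_patches,
                box_lengths, sigma, delta, cosmax, eps, beta,
                idx_a, idx_b, counts,
                dmax, rotmax, p_roto, p_avbb, vb,
                n_sweeps, n_transfer, vol_lnstep, total_volume,
                counters, gibbs_counters):
    """Gibbs-ensemble sweeps over two coupled boxes.

    Each sweep: N trial NVT-style moves split over the boxes in proportion
    to their populations, one volume-exchange move (uniform in ln(V1/V2)),
    and n_transfer particle transfer attempts.  box_lengths (2,) and counts
    (2,) are updated in place; idx_a / idx_b hold the particle ids of each
    box in their first counts[b] slots.  gibbs_counters: (vol_acc, vol_try,
    tr_acc, tr_try).
    """
    rcut2x = 2.0 * sigma * (1.0 + delta)
    for _ in range(n_sweeps):
        na, nb = counts[0], counts[1]
        n_tot = na + nb
        # NVT moves per box
        if na > 0:
            _run_moves(pos, patch, quat, species, colors, compat, body_patches,
                       box_lengths[0], sigma, delta, cosmax, eps, beta,
                       idx_a, na, dmax, rotmax, p_roto, p_avbb, vb, na, counters)
        if nb > 0:
            _run_moves(pos, patch, quat, species, colors, compat, body_patches,
                       box_lengths[1], sigma, delta, cosmax, eps, beta,
                       idx_b, nb, dmax, rotmax, p_roto, p_avbb, vb, nb, counters)
        # volume-exchange move
        gibbs_counters[1] += 1
        v1 = box_lengths[0] ** 3
        v2 = box_lengths[1] ** 3
        zeta = np.log(v1 / v2) + vol_lnstep * (2.0 * np.random.random() - 1.0)
        ez = np.exp(zeta)
        v1n = total_volume * ez / (1.0 + ez)
        v2n = total_volume - v1n
        l1n = v1n ** (1.0 / 3.0)
        l2n = v2n ** (1.0 / 3.0)
        if l1n > rcut2x and l2n > rcut2x:
            e1_old = total_energy_kernel(pos, patch, species, colors, compat,
                                         box_lengths[0], sigma, delta, cosmax,
                                         eps, idx_a, na)
            e2_old = total_energy_kernel(pos, patch, species, colors, compat,
                                         box_lengths[1], sigma, delta, cosmax,
                                         eps, idx_b, nb)
            s1 = l1n / box_lengths[0]
            s2 = l2n / box_lengths[1]
            for k in range(na):
                i = idx_a[k]
                for d in range(3):
                    pos[i, d] *= s1
            for k in range(nb):
                i = idx_b[k]
                for d in range(3):
                    pos[i, d] *= s2
            l1_old = box_lengths[0]
            l2_old = box_lengths[1]
            box_lengths[0] = l1n
            box_lengths[1] = l2n
            e1_new = total_energy_kernel(pos, patch, species, colors, compat,
                                         l1n, sigma, delta, cosmax, eps, idx_a, na)
            e2_new = total_energy_kernel(pos, patch, species, colors, compat,
                                         l2n, sigma, delta, cosmax, eps, idx_b, nb)
            accept = False
            if e1_new < BIG and e2_new < BIG:
                arg = (-beta * (e1_new - e1_old + e2_new - e2_old)
                       + (na + 1) * np.log(v1n / v1) + (nb + 1) * np.log(v2n / v2))
                if np.log(np.random.random() + 1e-300) < arg:
                    accept = True
            if accept:
                gibbs_counters[0] += 1
            else:
                box_lengths[0] = l1_old
                box_lengths[1] = l2_old
                inv1 = 1.0 / s1
                inv2 = 1.0 / s2
                for k in range(na):
                    i = idx_a[k]
                    for d in range(3):
                        pos[i, d] *= inv1
                for k in range(nb):
                    i = idx_b[k]
                    for d in range(3):
                        pos[i, d] *= inv2
        # particle transfers
        for _t in range(n_transfer):
            gibbs_counters[3] += 1
            src = 0 if np.random.random() < 0.5 else 1
            dst = 1 - src
            ns = counts[src]
            nd = counts[dst]
            if ns == 0:
                continue
            if src == 0:
                idx_s = idx_a
                idx_d = idx_b
            else:
                idx_s = idx_b
                idx_d = idx_a
            k_pick = int(np.random.random() * ns)
            i = idx_s[k_pick]
            e_rm = particle_energy(pos, patch, species, colors, compat,
                                   box_lengths[src], sigma, delta, cosmax, eps,
                                   idx_s, ns, i)
            # save pose
            opx, opy, opz = pos[i, 0], pos[i, 1], pos[i, 2]
            oq0, oq1, oq2, oq3 = quat[i, 0], quat[i, 1], quat[i, 2], quat[i, 3]
            npatch = patch.shape[1]
            saved = np.empty((npatch, 3))
            for a in range(npatch):
                for d in range(3):
                    saved[a, d] = patch[i, a, d]
            pos[i, 0] = box_lengths[dst] * np.random.random()
            pos[i, 1] = box_lengths[dst] * np.random.random()
            pos[i, 2] = box_lengths[dst] * np.random.random()
            qw, qx, qy, qz = _random_quat()
            _set_orientation(patch, quat, body_patches, species, i, qw, qx, qy, qz)
            e_ins = particle_energy(pos, patch, species, colors, compat,
                                    box_lengths[dst], sigma, delta, cosmax, eps,
                                    idx_d, nd, i)
            accept = False
            if e_ins < BIG:
                vs = box_lengths[src] ** 3
                vd = box_lengths[dst] ** 3
                arg = -beta * (e_ins - e_rm) + np.log((ns * vd) / ((nd + 1) * vs))
                if np.log(np.random.random() + 1e-300) < arg:
                    accept = True
            if accept:
                gibbs_counters[2] += 1
                idx_s[k_pick] = idx_s[ns - 1]
                idx_d[nd] = i
                counts[src] -= 1
                counts[dst] += 1
            else:
                pos[i, 0], pos[i, 1], pos[i, 2] = opx, opy, opz
                for a in range(npatch):
                    for d in range(3):
                        patch[i, a, d] = saved[a, d]
                quat[i, 0], quat[i, 1], quat[i, 2], quat[i, 3] = oq0, oq1, oq2, oq3
        _ = n_tot
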