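"""Numba force kernels for the bead-spring Langevin simulator.

All kernels use the minimum-image convention in a cubic periodic box of edge
``box``.  ``pair_forces`` requires positions wrapped into [0, box) (distances
between interacting pairs are then below box/2 and a branch min-image
suffices); the bonded kernels accept unwrapped positions.  Pair interactions
are truncated-shifted Lennard-Jones (WCA at the default cutoffs) with
per-pair-class parameters indexed by ``class_i + class_j`` (0 = monomer-
monomer, 1 = linker-monomer, 2 = linker-linker).  Bonds are FENE springs
combined with a WCA core at sigma = 1 (the Kremer-Grest convention); bonded
pairs are excluded from the pair table via per-particle exclusion lists.
"""

import math

import numpy as np
from numba import njit


@njit(cache=True)
def pair_forces(pos, cls, box, eps_t, sig_t, rc_t, excl, forces):
    """Accumulate nonbonded forces; returns the pair energy.

    Uses a linked-cell list when the box holds at least 3 cells per edge at
    the largest cutoff, otherwise the O(N^2) double loop.
    """
    n = pos.shape[0]
    rc_max = 0.0
    for t in range(3):
        if rc_t[t] > rc_max:
            rc_max = rc_t[t]
    ncell = int(box / rc_max)
    # cap the cell count so sparse systems with tiny cutoffs do not pay for
    # an enormous empty grid
    max_ncell = int(np.cbrt(4.0 * n)) + 1
    if ncell > max_ncell:
        ncell = max_ncell
    half = 0.5 * box
    energy = 0.0

    if ncell < 3:
        for i in range(n):
            for j in range(i + 1, n):
                dx = pos[i, 0] - pos[j, 0]
                dx -= box * round(dx / box)
                dy = pos[i, 1] - pos[j, 1]
                dy -= box * round(dy / box)
                dz = pos[i, 2] - pos[j, 2]
                dz -= box * round(dz / box)
                t = cls[i] + cls[j]
                rcv = rc_t[t]
                r2 = dx * dx + dy * dy + dz * dz
                if not (0.0 < r2 < rcv * rcv):
                    continue
                skip = False
                for m in range(excl.shape[1]):
                    if excl[i, m] == j:
                        skip = True
                        break
                    if excl[i, m] < 0:
                        break
                if skip:
                    continue
                e = eps_t[t]
                s = sig_t[t]
                s2 = s * s / r2
                s6 = s2 * s2 * s2
                s12 = s6 * s6
                src2 = s * s / (rcv * rcv)
                src6 = src2 * src2 * src2
                energy += 4.0 * e * (s12 - s6) - 4.0 * e * (src6 * src6 - src6)
                fr = (48.0 * e * s12 - 24.0 * e * s6) / r2
                forces[i, 0] += fr * dx
                forces[i, 1] += fr * dy
                forces[i, 2] += fr * dz
                forces[j, 0] -= fr * dx
                forces[j, 1] -= fr * dy
                forces[j, 2] -= fr * dz
        return energy

    inv_edge = ncell / box
    head = np.full(ncell * ncell * ncell, -1, dtype=np.int64)
    nxt = np.empty(n, dtype=np.int64)
    cell_of = np.empty(n, dtype=np.int64)
    for i in range(n):
        cx = int(pos[i, 0] * inv_edge)
        cy = int(pos[i, 1] * inv_edge)
        cz = int(pos[i, 2] * inv_edge)
        if cx >= ncell:
            cx = ncell - 1
        if cy >= ncell:
            cy = ncell - 1
        if cz >= ncell:
            cz = ncell - 1
        c = (cx * ncell + cy) * ncell + cz
        cell_of[i] = c
        nxt[i] = head[c]
        head[c] = i

    n2 = ncell * ncell
    for i in range(n):
        xi, yi, zi = pos[i, 0], pos[i, 1], pos[i, 2]
        ci = cls[i]
        c = cell_of[i]
        ccx = c // n2
        ccy = (c // ncell) % ncell
        ccz = c % ncell
        for ox in range(-1, 2):
            cx = ccx + ox
            if cx < 0:
                cx += ncell
            elif cx >= ncell:
                cx -= ncell
            for oy in range(-1, 2):
                cy = ccy + oy
                if cy < 0:
                    cy += ncell
                elif cy >= ncell:
                    cy -= ncell
                base = (cx * ncell + cy) * ncell
                for oz in range(-1, 2):
                    cz = ccz + oz
                    if cz < 0:
                        cz += ncell
                    elif cz >= ncell:
                        cz -= ncell
                    j = head[base + cz]
                    while j >= 0:
                        if j > i:
                            dx = xi - pos[j, 0]
                            if dx > half:
                                dx -= box
                            elif dx < -half:
                                dx += box
                            dy = yi - pos[j, 1]
                            if dy > half:
                                dy -= box
                            elif dy < -half:
                                dy += box
                            dz = zi - pos[j, 2]
                            if dz > half:
                                dz -= box
                            elif dz < -half:
                                dz += box
                            t = ci + cls[j]
                            rcv = rc_t[t]
                            r2 = dx * dx + dy * dy + dz * dz
                            if 0.0 < r2 < rcv * rcv:
                                skip = False
                                for m in range(excl.shape[1]):
                                    if excl[i, m] == j:
                                        skip = True
                                        break
                                    if excl[i, m] < 0:
                                        break
                                if not skip:
                                    e = eps_t[t]
                                    s = sig_t[t]
                                    s2 = s * s / r2
                                    s6 = s2 * s2 * s2
                                    s12 = s6 * s6
                                    src2 = s * s / (rcv * rcv)
                                    src6 = src2 * src2 * src2
                                    energy += (
                                        4.0 * e * (s12 - s6)
                                        - 4.0 * e * (src6 * src6 - src6)
                                    )
                                    fr = (48.0 * e * s12 - 24.0 * e * s6) / r2
                                    forces[i, 0] += fr * dx
                                    forces[i, 1] += fr * dy
                                    forces[i, 2] += fr * dz
                                    forces[j, 0] -= fr * dx
                                    forces[j, 1] -= fr * dy
                                    forces[j, 2] -= fr * dz
                        j = nxt[j]
    return energy


@njit(cache=True)
def bond_forces(pos, bonds, n_core, box, k, R0, forces):
    """FENE bond forces; returns (energy, first overstretched bond).

    The first ``n_core`` rows (permanent bonds, whose pairs are excluded from
    the pair table) additionally carry a WCA core at sigma = 1, the
    Kremer-Grest convention; later rows (dynamic cross-links, whose pairs keep
    their nonbonded repulsion) are bare FENE.  The second return value is -1
    when all extensions are below R0; otherwise the offending row index into
    ``bonds`` (forces are then unreliable and the caller must abort the step).
    """
    energy = 0.0
    bad = -1
    R02 = R0 * R0
    wca_rc2 = 2.0 ** (1.0 / 3.0)  # (2^{1/6})^2 for sigma = 1
    for b in range(bonds.shape[0]):
        i = bonds[b, 0]
        j = bonds[b, 1]
        dx = pos[i, 0] - pos[j, 0]
        dy = pos[i, 1] - pos[j, 1]
        dz = pos[i, 2] - pos[j, 2]
        dx -= box * round(dx / box)
        dy -= box * round(dy / box)
        dz -= box * round(dz / box)
        r2 = dx * dx + dy * dy + dz * dz
        if r2 >= R02:
            bad = b
            continue
        ratio = r2 / R02
        energy += -0.5 * k * R02 * math.log(1.0 - ratio)
        f_over_r = -k / (1.0 - ratio)  # attractive
        if b < n_core and 0.0 < r2 < wca_rc2:
            inv6 = 1.0 / (r2 * r2 * r2)
            energy += 4.0 * (inv6 * inv6 - inv6) + 1.0
            f_over_r += (48.0 * inv6 * inv6 - 24.0 * inv6) / r2
        forces[i, 0] += f_over_r * dx
        forces[i, 1] += f_over_r * dy
        forces[i, 2] += f_over_r * dz
        forces[j, 0] -= f_over_r * dx
        forces[j, 1] -= f_over_r * dy
        forces[j, 2] -= f_over_r * dz
    return energy, bad


@njit(cache=True)
def angle_forces(pos, angles, box, k_theta, forces):
    """Cosine bending forces, U = k_theta (1 - cos theta); returns the energy.

    ``theta`` is the deviation from a straight triplet: cos theta is the dot
    product of the two consecutive unit bond vectors, so collinear bonds cost
    nothing and the potential stiffens the chain.
    """
    energy = 0.0
    for a in range(angles.shape[0]):
        i = angles[a, 0]
        j = angles[a, 1]
        l = angles[a, 2]
        b1x = pos[j, 0] - pos[i, 0]
        b1y = pos[j, 1] - pos[i, 1]
        b1z = pos[j, 2] - pos[i, 2]
        b1x -= box * round(b1x / box)
        b1y -= box * round(b1y / box)
        b1z -= box * round(b1z / box)
        b2x = pos[l, 0] - pos[j, 0]
        b2y = pos[l, 1] - pos[j, 1]
        b2z = pos[l, 2] - pos[j, 2]
        b2x -= box * round(b2x / box)
        b2y -= box * round(b2y / box)
        b2z -= box * round(b2z / box)
        n1 = math.sqrt(b1x * b1x + b1y * b1y + b1z * b1z)
        n2 = math.sqrt(b2x * b2x + b2y * b2y + b2z * b2z)
        if n1 == 0.0 or n2 == 0.0:
            continue
        e1x, e1y, e1z = b1x / n1, b1y / n1, b1z / n1
        e2x, e2y, e2z = b2x / n2, b2y / n2, b2z / n2
        c = e1x * e2x + e1y * e2y + e1z * e2z
        energy += k_theta * (1.0 - c)
        # F = +k_theta * grad(cos theta)
        # d(cos)/db1 = (e2 - c e1)/n1 ; d(cos)/db2 = (e1 - c e2)/n2
        g1x = (e2x - c * e1x) / n1
        g1y = (e2y - c * e1y) / n1
        g1z = (e2z - c * e1z) / n1
        g2x = (e1x - c * e2x) / n2
        g2y = (e1y - c * e2y) / n2
        g2z = (e1z - c * e2z) / n2
        # r_i enters b1 with -1; r_l enters b2 with +1; r_j with (+1, -1)
        forces[i, 0] -= k_theta * g1x
        forces[i, 1] -= k_theta * g1y
        forces[i, 2] -= k_theta * g1z
        forces[j, 0] += k_theta * (g1x - g2x)
        forces[j, 1] += k_theta * (g1y - g2y)
        forces[j, 2] += k_theta * (g1z - g2z)
        forces[l, 0] += k_theta * g2x
        forces[l, 1] += k_theta * g2y
        forces[l, 2] += k_theta * g2z
    return energy
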