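"""Numba kernel for the confined lattice ring polymer (bond-fluctuation model).

Each monomer occupies a 2x2x2 cube of lattice sites; bonds between ring
neighbours (and between looped partners) must have squared length in
{4, 5, 6, 9, 10} (the classic three-dimensional bond set, which excludes
chain crossing).  Moves are single-monomer displacements by one site along
a random axis, rejected on wall contact (hard reflecting walls on all six
faces), overlap of monomer cubes, bond violation, or violation of an active
loop constraint.  One Monte-Carlo step (MCS) is N attempted moves followed
by one loop update: expired loops are removed and, while an *ori* has fewer
than its maximum number of loops, one uniformly chosen candidate within
bond range (excluding its +-2 ring neighbours) may form a loop with a
probability set by the *ori*'s relative long-axis position.
"""

import numpy as np
from numba import njit

from ._ssa import _u01

#: squared bond lengths allowed by the 3-D bond-fluctuation model
ALLOWED_B2 = np.zeros(11, dtype=np.uint8)
for _b2 in (4, 5, 6, 9, 10):
    ALLOWED_B2[_b2] = 1


@njit(cache=True, inline="always")
def _site(x, y, z, Y, Z):
    return (x * Y + y) * Z + z


@njit(cache=True, inline="always")
def _bond_ok(ax, ay, az, bx, by, bz):
    dx = ax - bx
    dy = ay - by
    dz = az - bz
    d2 = dx * dx + dy * dy + dz * dz
    return 4 <= d2 <= 10 and d2 != 7 and d2 != 8


@njit(cache=True)
def build_occupancy(pos, X, Y, Z):
    occ = np.zeros(X * Y * Z, dtype=np.uint8)
    for m in range(pos.shape[0]):
        for dx in range(2):
            for dy in range(2):
                for dz in range(2):
                    s = _site(pos[m, 0] + dx, pos[m, 1] + dy, pos[m, 2] + dz,
                              Y, Z)
                    if occ[s]:
                        return occ, False
                    occ[s] = 1
    return occ, True


@njit(cache=True)
def check_conformation(pos, ring_next, X, Y, Z):
    """Validate walls, excluded volume and all ring bonds; returns bool."""
    n = pos.shape[0]
    for m in range(n):
        if (pos[m, 0] < 0 or pos[m, 0] > X - 2 or pos[m, 1] < 0
                or pos[m, 1] > Y - 2 or pos[m, 2] < 0 or pos[m, 2] > Z - 2):
            return False
        nx = ring_next[m]
        if not _bond_ok(pos[m, 0], pos[m, 1], pos[m, 2],
                        pos[nx, 0], pos[nx, 1], pos[nx, 2]):
            return False
    _, ok = build_occupancy(pos, X, Y, Z)
    return ok


@njit(cache=True, inline="always")
def _move_ok(m, axis, step, pos, occ, ring_next, ring_prev, partner_of,
             ori_idx, loop_partner, X, Y, Z):
    c0 = pos[m, axis]
    nc = c0 + step
    dim = X if axis == 0 else (Y if axis == 1 else Z)
    if nc < 0 or nc > dim - 2:
        return False
    # the 4 sites of the leading plane must be free
    if axis == 0:
        px = c0 + 2 if step > 0 else c0 - 1
        for dy in range(2):
            for dz in range(2):
                if occ[_site(px, pos[m, 1] + dy, pos[m, 2] + dz, Y, Z)]:
                    return False
    elif axis == 1:
        py = c0 + 2 if step > 0 else c0 - 1
        for dx in range(2):
            for dz in range(2):
                if occ[_site(pos[m, 0] + dx, py, pos[m, 2] + dz, Y, Z)]:
                    return False
    else:
        pz = c0 + 2 if step > 0 else c0 - 1
        for dx in range(2):
            for dy in range(2):
                if occ[_site(pos[m, 0] + dx, pos[m, 1] + dy, pz, Y, Z)]:
                    return False
    ax, ay, az = pos[m, 0], pos[m, 1], pos[m, 2]
    if axis == 0:
        ax = nc
    elif axis == 1:
        ay = nc
    else:
        az = nc
    for nb in (ring_prev[m], ring_next[m]):
        if not _bond_ok(ax, ay, az, pos[nb, 0], pos[nb, 1], pos[nb, 2]):
            return False
    # loop constraints: m may be an ori (check its partners) or a partner
    for o in range(ori_idx.shape[0]):
        if ori_idx[o] == m:
            for l in range(loop_partner.shape[1]):
                p = loop_partner[o, l]
                if p >= 0 and not _bond_ok(ax, ay, az, pos[p, 0], pos[p, 1],
                                           pos[p, 2]):
                    return False
    if partner_of[m] >= 0:
        o = partner_of[m] // loop_partner.shape[1]
        oi = ori_idx[o]
        if not _bond_ok(ax, ay, az, pos[oi, 0], pos[oi, 1], pos[oi, 2]):
            return False
    return True


@njit(cache=True)
def sweep(pos, occ, ring_next, ring_prev, partner_of, ori_idx, loop_partner,
          X, Y, Z, rs):
    """One MCS: N single-monomer move attempts; returns accepted count."""
    n = pos.shape[0]
    accepted = 0
    for _ in range(n):
        m = int(_u01(rs) * n)
        r = _u01(rs)
        axis = int(r * 3.0)
        step = 1 if _u01(rs) < 0.5 else -1
        if _move_ok(m, axis, step, pos, occ, ring_next, ring_prev,
                    partner_of, ori_idx, loop_partner, X, Y, Z):
            c0 = pos[m, axis]
            # update occupancy: clear trailing plane, set leading plane
            if axis == 0:
                old = c0 if step > 0 else c0 + 1
                new = c0 + 2 if step > 0 else c0 - 1
                for dy in range(2):
                    for dz in range(2):
                        occ[_site(old, pos[m, 1] + dy, pos[m, 2] + dz, Y, Z)] = 0
                        occ[_site(new, pos[m, 1] + dy, pos[m, 2] + dz, Y, Z)] = 1
            elif axis == 1:
                old = c0 if step > 0 else c0 + 1
                new = c0 + 2 if step > 0 else c0 - 1
                for dx in range(2):
                    for dz in range(2):
                        occ[_site(pos[m, 0] + dx, old, pos[m, 2] + dz, Y, Z)] = 0
                        occ[_site(pos[m, 0] + dx, new, pos[m, 2] + dz, Y, Z)] = 1
            else:
                old = c0 if step > 0 else c0 + 1
                new = c0 + 2 if step > 0 else c0 - 1
                for dx in range(2):
                    for dy in range(2):
                        occ[_site(pos[m, 0] + dx, pos[m, 1] + dy, old, Y, Z)] = 0
                        occ[_site(pos[m, 0] + dx, pos[m, 1] + dy, new, Y, Z)] = 1
            pos[m, axis] = c0 + step
            accepted += 1
    return accepted


@njit(cache=True)
def loop_probability(x_rel, centres, inv2sd2, p_max):
    p = 0.0
    for c in range(centres.shape[0]):
        d = x_rel - centres[c]
        p += p_max * np.exp(-d * d * inv2sd2)
    return min(p, 1.0)


@njit(cache=True)
def update_loops(now, pos, ring_next, ring_prev, partner_of, ori_idx,
                 loop_partner, loop_expiry, centres, inv2sd2, p_max,
                 lifetime, Z, rs, cand_buf):
    """Remove expired loops; let each under-occupied ori attempt one loop."""
    n = pos.shape[0]
    max_loops = loop_partner.shape[1]
    for o in range(ori_idx.shape[0]):
        free_slot = -1
        n_active = 0
        for l in range(max_loops):
            p = loop_partner[o, l]
            if p >= 0 and loop_expiry[o, l] <= now:
                partner_of[p] = -1
                loop_partner[o, l] = -1
            if loop_partner[o, l] >= 0:
                n_active += 1
            elif free_slot < 0:
                free_slot = l
        if n_active >= max_loops or p_max <= 0.0:
            continue
        oi = ori_idx[o]
        # candidates: within bond range, not ring-adjacent (+-2), not an ori,
        # not already partnered
        nc = 0
        ex1 = ring_next[oi]
        ex2 = ring_next[ex1]
        ex3 = ring_prev[oi]
        ex4 = ring_prev[ex3]
        for m in range(n):
            if m == oi or m == ex1 or m == ex2 or m == ex3 or m == ex4:
                continue
            if partner_of[m] >= 0:
                continue
            is_ori = False
            for o2 in range(ori_idx.shape[0]):
                if ori_idx[o2] == m:
                    is_ori = True
                    break
            if is_ori:
                continue
            if _bond_ok(pos[oi, 0], pos[oi, 1], pos[oi, 2],
                        pos[m, 0], pos[m, 1], pos[m, 2]):
                cand_buf[nc] = m
                nc += 1
        if nc == 0:
            continue
        m = cand_buf[int(_u01(rs) * nc)]
        x_rel = (pos[oi, 2] + 1.0) / Z - 0.5
        if _u01(rs) < loop_probability(x_rel, centres, inv2sd2, p_max):
            loop_partner[o, free_slot] = m
            loop_expiry[o, free_slot] = now + lifetime
            partner_of[m] = o * max_loops + free_slot


@njit(cache=True)
def run_traj(pos, occ, ring_next, ring_prev, partner_of, ori_idx,
             loop_partner, loop_expiry, X, Y, Z, centres, inv2sd2, p_max,
             lifetime, readout_every, n_readouts, rs, out_zrel, cand_buf):
    """Run MCS sweeps, recording ori relative z at every readout."""
    now = 0
    for r in range(n_readouts):
        for _ in range(readout_every):
            sweep(pos, occ, ring_next, ring_prev, partner_of, ori_idx,
                  loop_partner, X, Y, Z, rs)
            now += 1
            update_loops(now, pos, ring_next, ring_prev, partner_of, ori_idx,
                         loop_partner, loop_expiry, centres, inv2sd2, p_max,
                         lifetime, Z, rs, cand_buf)
        for o in range(ori_idx.shape[0]):
            out_zrel[r, o] = (pos[ori_idx[o], 2] + 1.0) / Z - 0.5
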