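"""Numba kernel for the exact spatial Gillespie (RDME) simulation.

The long cell axis is discretised into ``n_comp`` compartments of width h.
Species u and v react and hop between neighbouring compartments (reflecting
boundaries); species w is well-mixed and treated as a single count.  *ori*
particles live on a finer sub-compartment lattice (``n_sub`` sub-compartments
per compartment) and perform a biased random walk whose jump rates depend on
the linearly interpolated v-profile and, optionally, on a sister-repulsion
bias.

Event selection is exact: a two-level linear search - blocks of 8
compartments, then compartments, then the reaction/diffusion channels within
the selected compartment - with the ori jump channels appended after the
compartments.  Channel propensities are recomputed from the integer counts
on every change and all running partial sums are refreshed periodically, so
floating-point drift cannot accumulate.  Randomness comes from an inline
xoshiro256+ 64-bit generator (seeded per run via splitmix64), giving enough
significant digits to resolve reactions with very low relative rates such
as the ori jumps.

Channel layout per compartment::

    0  u -> v      alpha*u + beta_hat*u*v*(v-1)
    1  v -> u      gamma*v
    2  u -> w      delta*u
    3  w -> u      epsilon*w*g[i]     (g = loading weights, sum 1)
    4  u hop left  (D_u/h^2)*u        5  u hop right
    6  v hop left  (D_v/h^2)*v        7  v hop right
    8  v -> w      delta*v            (optional channel, 0 unless enabled)

Scalar parameter vector ``P`` (float64)::

    0 alpha  1 beta_hat  2 gamma  3 delta  4 epsilon
    5 D_u/h^2  6 D_v/h^2  7 v_to_w flag  8 mu/(n_sub*h)  9 D_ori/h_s^2
    10 k_rep*h_s/(2*D_ori)  11 1/sigma_rep  12 h_s  13 loading_ratio

Integer state vector ``SI``:: 0 n_comp, 1 w, 2 n_ori, 3 event count, 4 error flag
Float state vector ``SF``::   0 t, 1 ctot (compartment total), 2 otot (ori total)
"""

import numpy as np
from numba import njit

NCHAN = 9
MAX_ORI = 4

# indices into P
P_ALPHA, P_BHAT, P_GAMMA, P_DELTA, P_EPS = 0, 1, 2, 3, 4
P_DU, P_DV, P_V2W, P_MUH, P_DHS2 = 5, 6, 7, 8, 9
P_KREPF, P_INVSIG, P_HS, P_RATIO = 10, 11, 12, 13

STOP_TIME = 0
STOP_ERROR = 1

#: half-width of the precomputed jump-rate table over integer v differences
OTAB_HALF = 512

_INV53 = 1.0 / 9007199254740992.0  # 2^-53


def make_rng_state(seed: int) -> np.ndarray:
    """Initialise xoshiro256+ state from a seed via splitmix64."""
    state = np.empty(4, dtype=np.uint64)
    mask = (1 << 64) - 1
    x = int(seed) & mask
    for i in range(4):
        x = (x + 0x9E3779B97F4A7C15) & mask
        z = x
        z = ((z ^ (z >> 30)) * 0xBF58476D1CE4E5B9) & mask
        z = ((z ^ (z >> 27)) * 0x94D049BB133111EB) & mask
        z = z ^ (z >> 31)
        state[i] = z
    if not state.any():
        state[0] = np.uint64(1)
    return state


@njit(cache=True, inline="always")
def _u01(rs):
    """Next double in [0, 1) from xoshiro256+ state ``rs`` (uint64[4])."""
    result = rs[0] + rs[3]
    t = rs[1] << np.uint64(17)
    rs[2] ^= rs[0]
    rs[3] ^= rs[1]
    rs[1] ^= rs[2]
    rs[0] ^= rs[3]
    rs[2] ^= t
    rs[3] = (rs[3] << np.uint64(45)) | (rs[3] >> np.uint64(19))
    return (result >> np.uint64(11)) * _INV53


@njit(cache=True, inline="always")
def _jump_rate(a, dhs2):
    """Biased jump rate (D/h_s^2) * a / (1 - exp(-a)), overflow-safe."""
    if a > 700.0:
        return dhs2 * a
    if a < -700.0:
        return 0.0
    if -1e-9 < a < 1e-9:
        return dhs2 * (1.0 + 0.5 * a)
    return dhs2 * a / (1.0 - np.exp(-a))


@njit(cache=True)
def interp_v(v, j, n_comp, n_sub):
    """v at sub-compartment j: piecewise-linear between compartment centres,
    constant beyond the outermost centres (reference helper)."""
    half = (n_sub - 1) // 2
    if j <= half:
        return float(v[0])
    if j >= (n_comp - 1) * n_sub + half:
        return float(v[n_comp - 1])
    i = (j - half) // n_sub
    frac = (j - (i * n_sub + half)) / n_sub
    return v[i] + frac * (v[i + 1] - v[i])


@njit(cache=True, inline="always")
def _ori_rates(k, v, ori_pos, ori_comp, ori_sister, oF, oB, otab,
               n_comp, n_sub, half, mu_h, dhs2, krepf, invsig, hsub):
    """Recompute forward/backward jump rates of ori k; returns rate delta.

    Without sister repulsion the bias is mu/h times an integer v difference,
    so rates come from the precomputed table ``otab`` (index = difference +
    OTAB_HALF); with repulsion active the rate formula is evaluated directly.
    """
    j = ori_pos[k]
    nmax = n_comp * n_sub
    ic = ori_comp[k]
    off = j - ic * n_sub
    # segment of the sub-pair (j, j+1): compartment ic if the pair lies right
    # of ic's centre, else ic-1; flat extrapolation beyond the outer centres
    i_f = ic if off >= half else ic - 1
    df = float(v[i_f + 1] - v[i_f]) if 0 <= i_f < n_comp - 1 else 0.0
    i_b = ic if off - 1 >= half else ic - 1
    db = float(v[i_b + 1] - v[i_b]) if 0 <= i_b < n_comp - 1 else 0.0
    s = ori_sister[k]
    rep = s >= 0 and krepf > 0.0
    if not rep:
        newF = 0.0 if j >= nmax - 1 else otab[int(df) + OTAB_HALF]
        newB = 0.0 if j <= 0 else otab[OTAB_HALF - int(db)]
    else:
        a_f = mu_h * df
        a_b = -mu_h * db
        d = abs(ori_pos[k] - ori_pos[s]) * hsub
        if d > 0.0:
            x = d * invsig
            arep = krepf * d * np.exp(-0.5 * x * x)
            if ori_pos[k] > ori_pos[s]:
                a_f += arep
                a_b -= arep
            else:
                a_f -= arep
                a_b += arep
        newF = 0.0 if j >= nmax - 1 else _jump_rate(a_f, dhs2)
        newB = 0.0 if j <= 0 else _jump_rate(a_b, dhs2)
    delta = (newF - oF[k]) + (newB - oB[k])
    oF[k] = newF
    oB[k] = newB
    return delta


@njit(cache=True)
def compute_loading_weights(g, n_comp, ori_pos, n_ori, n_sub, ratio):
    """Per-compartment loading weights: ratio/Z in ori compartments, 1/Z else."""
    n_occ = 0
    for i in range(n_comp):
        g[i] = 1.0
    if ratio > 1.0:
        # mark ori-containing compartments (counted once each)
        for k in range(n_ori):
            i = ori_pos[k] // n_sub
            if g[i] == 1.0:
                g[i] = ratio
                n_occ += 1
    Z = (n_comp - n_occ) + ratio * n_occ
    for i in range(n_comp):
        g[i] /= Z


@njit(cache=True, inline="always")
def _upd_after_u(i, u, v, prop, comp_sum, n_comp, alpha, bhat, delta_r, du):
    """Refresh the channels that depend on u[i]; returns comp_sum delta."""
    uu = float(u[i])
    vv = float(v[i])
    p0 = alpha * uu + bhat * uu * vv * (vv - 1.0)
    p2 = delta_r * uu
    p4 = du * uu if i > 0 else 0.0
    p5 = du * uu if i < n_comp - 1 else 0.0
    d = (p0 - prop[i, 0]) + (p2 - prop[i, 2]) + (p4 - prop[i, 4]) \
        + (p5 - prop[i, 5])
    prop[i, 0] = p0
    prop[i, 2] = p2
    prop[i, 4] = p4
    prop[i, 5] = p5
    comp_sum[i] += d
    return d


@njit(cache=True, inline="always")
def _upd_after_v(i, u, v, prop, comp_sum, n_comp, alpha, bhat, gamma, dv,
                 delta_v2w):
    """Refresh the channels that depend on v[i]; returns comp_sum delta."""
    uu = float(u[i])
    vv = float(v[i])
    p0 = alpha * uu + bhat * uu * vv * (vv - 1.0)
    p1 = gamma * vv
    p6 = dv * vv if i > 0 else 0.0
    p7 = dv * vv if i < n_comp - 1 else 0.0
    p8 = delta_v2w * vv
    d = (p0 - prop[i, 0]) + (p1 - prop[i, 1]) + (p6 - prop[i, 6]) \
        + (p7 - prop[i, 7]) + (p8 - prop[i, 8])
    prop[i, 0] = p0
    prop[i, 1] = p1
    prop[i, 6] = p6
    prop[i, 7] = p7
    prop[i, 8] = p8
    comp_sum[i] += d
    return d


@njit(cache=True, inline="always")
def _w_changed(w, g, eps, prop, comp_sum, gsum, n_comp):
    """Refresh the w -> u channel everywhere, tracking group sums."""
    delta = 0.0
    for i in range(n_comp):
        p3 = eps * w * g[i]
        d = p3 - prop[i, 3]
        prop[i, 3] = p3
        comp_sum[i] += d
        gsum[i >> 3] += d
        delta += d
    return delta


@njit(cache=True)
def _refresh(prop, comp_sum, gsum, n_comp, ngrp):
    ctot = 0.0
    for i in range(n_comp):
        s = 0.0
        for c in range(NCHAN):
            s += prop[i, c]
        comp_sum[i] = s
        ctot += s
    for gb in range(ngrp):
        s = 0.0
        hi = min((gb << 3) + 8, n_comp)
        for i in range(gb << 3, hi):
            s += comp_sum[i]
        gsum[gb] = s
    return ctot


@njit(cache=True)
def rebuild_all(u, v, prop, comp_sum, gsum, g, ori_pos, ori_comp, ori_sister,
                oF, oB, P, SI, SF, n_sub, otab):
    """Recompute every propensity from scratch (after init/growth/duplication)."""
    n_comp = SI[0]
    w = float(SI[1])
    n_ori = SI[2]
    half = (n_sub - 1) // 2
    compute_loading_weights(g, n_comp, ori_pos, n_ori, n_sub, P[P_RATIO])
    for i in range(n_comp):
        uu = float(u[i])
        vv = float(v[i])
        prop[i, 0] = P[P_ALPHA] * uu + P[P_BHAT] * uu * vv * (vv - 1.0)
        prop[i, 1] = P[P_GAMMA] * vv
        prop[i, 2] = P[P_DELTA] * uu
        prop[i, 3] = P[P_EPS] * w * g[i]
        prop[i, 4] = P[P_DU] * uu if i > 0 else 0.0
        prop[i, 5] = P[P_DU] * uu if i < n_comp - 1 else 0.0
        prop[i, 6] = P[P_DV] * vv if i > 0 else 0.0
        prop[i, 7] = P[P_DV] * vv if i < n_comp - 1 else 0.0
        prop[i, 8] = P[P_DELTA] * vv if P[P_V2W] > 0.0 else 0.0
    ngrp = (n_comp + 7) >> 3
    SF[1] = _refresh(prop, comp_sum, gsum, n_comp, ngrp)
    otot = 0.0
    for k in range(n_ori):
        ori_comp[k] = ori_pos[k] // n_sub
        oF[k] = 0.0
        oB[k] = 0.0
        _ori_rates(k, v, ori_pos, ori_comp, ori_sister, oF, oB, otab,
                   n_comp, n_sub, half, P[P_MUH], P[P_DHS2], P[P_KREPF],
                   P[P_INVSIG], P[P_HS])
        otot += oF[k] + oB[k]
    for k in range(n_ori, MAX_ORI):
        oF[k] = 0.0
        oB[k] = 0.0
    SF[2] = otot


@njit(cache=True)
def run_until(t_stop, u, v, prop, comp_sum, gsum, g, ori_pos, ori_comp,
              ori_sister, oF, oB, P, SI, SF, n_sub, otab, rs):
    """Advance the exact SSA to t_stop.  Returns STOP_TIME or STOP_ERROR."""
    n_comp = SI[0]
    w = float(SI[1])
    t = SF[0]
    ctot = SF[1]
    otot = SF[2]
    n_ori = SI[2]
    events = SI[3]
    ngrp = (n_comp + 7) >> 3
    half = (n_sub - 1) // 2
    # hoist parameters into registers (array loads would be reloaded after
    # every propensity store because float64 arrays may alias)
    alpha = P[P_ALPHA]
    bhat = P[P_BHAT]
    gamma = P[P_GAMMA]
    delta_r = P[P_DELTA]
    eps = P[P_EPS]
    du = P[P_DU]
    dv = P[P_DV]
    delta_v2w = delta_r if P[P_V2W] > 0.0 else 0.0
    mu_h = P[P_MUH]
    dhs2 = P[P_DHS2]
    krepf = P[P_KREPF]
    invsig = P[P_INVSIG]
    hsub = P[P_HS]
    ratio = P[P_RATIO]
    while True:
        total = ctot + otot
        if total <= 0.0:
            nmol = SI[1]
            for i in range(n_comp):
                nmol += u[i] + v[i]
            if nmol > 0:
                SI[4] = 1
                SF[0] = t
                SI[3] = events
                return STOP_ERROR
            SF[0] = t_stop
            SI[3] = events
            return STOP_TIME
        tau = -np.log(_u01(rs)) / total
        if t + tau > t_stop:
            SF[0] = t_stop
            SF[1] = ctot
            SF[2] = otot
            SI[3] = events
            return STOP_TIME
        t += tau
        events += 1
        r = _u01(rs) * total
        # level 1: blocks of 8 compartments; level 2: compartments
        i = -1
        acc = 0.0
        for gb in range(ngrp):
            if acc + gsum[gb] > r:
                r -= acc
                base = gb << 3
                top = min(base + 8, n_comp)
                acc2 = 0.0
                for c in range(base, top):
                    if acc2 + comp_sum[c] > r:
                        i = c
                        r -= acc2
                        break
                    acc2 += comp_sum[c]
                if i < 0:
                    i = top - 1
                    r -= acc2 - comp_sum[i]
                break
            acc += gsum[gb]
        if i >= 0:
            # level 3: channel within compartment i
            ch = NCHAN - 1
            acc = 0.0
            for c in range(NCHAN):
                if acc + prop[i, c] > r:
                    ch = c
                    break
                acc += prop[i, c]
            gi = i >> 3
            if ch == 4 or ch == 5:     # u hop (most frequent event class)
                j = i - 1 if ch == 4 else i + 1
                u[i] -= 1
                u[j] += 1
                d = _upd_after_u(i, u, v, prop, comp_sum, n_comp, alpha, bhat,
                                 delta_r, du)
                gsum[gi] += d
                ctot += d
                d = _upd_after_u(j, u, v, prop, comp_sum, n_comp, alpha, bhat,
                                 delta_r, du)
                gsum[j >> 3] += d
                ctot += d
            elif ch == 0:              # u -> v
                u[i] -= 1
                v[i] += 1
                d = _upd_after_u(i, u, v, prop, comp_sum, n_comp, alpha, bhat,
                                 delta_r, du)
                d += _upd_after_v(i, u, v, prop, comp_sum, n_comp, alpha,
                                  bhat, gamma, dv, delta_v2w)
                gsum[gi] += d
                ctot += d
                for k in range(n_ori):
                    if ori_comp[k] - 1 <= i <= ori_comp[k] + 1:
                        otot += _ori_rates(k, v, ori_pos, ori_comp,
                                           ori_sister, oF, oB, otab, n_comp,
                                           n_sub, half, mu_h, dhs2, krepf,
                                           invsig, hsub)
            elif ch == 1:              # v -> u
                v[i] -= 1
                u[i] += 1
                d = _upd_after_u(i, u, v, prop, comp_sum, n_comp, alpha, bhat,
                                 delta_r, du)
                d += _upd_after_v(i, u, v, prop, comp_sum, n_comp, alpha,
                                  bhat, gamma, dv, delta_v2w)
                gsum[gi] += d
                ctot += d
                for k in range(n_ori):
                    if ori_comp[k] - 1 <= i <= ori_comp[k] + 1:
                        otot += _ori_rates(k, v, ori_pos, ori_comp,
                                           ori_sister, oF, oB, otab, n_comp,
                                           n_sub, half, mu_h, dhs2, krepf,
                                           invsig, hsub)
            elif ch == 6 or ch == 7:   # v hop
                j = i - 1 if ch == 6 else i + 1
                v[i] -= 1
                v[j] += 1
                d = _upd_after_v(i, u, v, prop, comp_sum, n_comp, alpha, bhat,
                                 gamma, dv, delta_v2w)
                gsum[gi] += d
                ctot += d
                d = _upd_after_v(j, u, v, prop, comp_sum, n_comp, alpha, bhat,
                                 gamma, dv, delta_v2w)
                gsum[j >> 3] += d
                ctot += d
                lo = i if i < j else j
                hi = i if i > j else j
                for k in range(n_ori):
                    if ori_comp[k] - 1 <= hi and lo <= ori_comp[k] + 1:
                        otot += _ori_rates(k, v, ori_pos, ori_comp,
                                           ori_sister, oF, oB, otab, n_comp,
                                           n_sub, half, mu_h, dhs2, krepf,
                                           invsig, hsub)
            elif ch == 2:              # u -> w
                u[i] -= 1
                SI[1] += 1
                w = float(SI[1])
                d = _upd_after_u(i, u, v, prop, comp_sum, n_comp, alpha, bhat,
                                 delta_r, du)
                gsum[gi] += d
                ctot += d
                ctot += _w_changed(w, g, eps, prop, comp_sum, gsum, n_comp)
            elif ch == 3:              # w -> u
                SI[1] -= 1
                w = float(SI[1])
                u[i] += 1
                d = _upd_after_u(i, u, v, prop, comp_sum, n_comp, alpha, bhat,
                                 delta_r, du)
                gsum[gi] += d
                ctot += d
                ctot += _w_changed(w, g, eps, prop, comp_sum, gsum, n_comp)
            else:                      # v -> w (optional channel)
                v[i] -= 1
                SI[1] += 1
                w = float(SI[1])
                d = _upd_after_v(i, u, v, prop, comp_sum, n_comp, alpha, bhat,
                                 gamma, dv, delta_v2w)
                gsum[gi] += d
                ctot += d
                ctot += _w_changed(w, g, eps, prop, comp_sum, gsum, n_comp)
                for k in range(n_ori):
                    if ori_comp[k] - 1 <= i <= ori_comp[k] + 1:
                        otot += _ori_rates(k, v, ori_pos, ori_comp,
                                           ori_sister, oF, oB, otab, n_comp,
                                           n_sub, half, mu_h, dhs2, krepf,
                                           invsig, hsub)
        else:
            # ori jump channels
            rr = r - acc
            k_sel = -1
            fwd = True
            acc2 = 0.0
            for k in range(n_ori):
                if acc2 + oF[k] > rr:
                    k_sel = k
                    fwd = True
                    break
                acc2 += oF[k]
                if acc2 + oB[k] > rr:
                    k_sel = k
                    fwd = False
                    break
                acc2 += oB[k]
            if k_sel < 0:
                # numerical slack at the end of the table: refresh totals
                ctot = _refresh(prop, comp_sum, gsum, n_comp, ngrp)
                otot = 0.0
                for k in range(n_ori):
                    otot += oF[k] + oB[k]
                continue
            ori_pos[k_sel] += 1 if fwd else -1
            new_comp = ori_pos[k_sel] // n_sub
            if new_comp != ori_comp[k_sel]:
                ori_comp[k_sel] = new_comp
                if ratio > 1.0:
                    compute_loading_weights(g, n_comp, ori_pos, n_ori, n_sub,
                                            ratio)
                    ctot += _w_changed(w, g, eps, prop, comp_sum, gsum,
                                       n_comp)
            otot += _ori_rates(k_sel, v, ori_pos, ori_comp, ori_sister, oF,
                               oB, otab, n_comp, n_sub, half, mu_h, dhs2,
                               krepf, invsig, hsub)
            s = ori_sister[k_sel]
            if s >= 0 and krepf > 0.0:
                otot += _ori_rates(s, v, ori_pos, ori_comp, ori_sister, oF,
                                   oB, otab, n_comp, n_sub, half, mu_h, dhs2,
                                   krepf, invsig, hsub)
        if (events & 0xFFFFF) == 0:
            # periodic exact refresh of partial sums (float drift control)
            ctot = _refresh(prop, comp_sum, gsum, n_comp, ngrp)
            otot = 0.0
            for k in range(n_ori):
                otot += oF[k] + oB[k]
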