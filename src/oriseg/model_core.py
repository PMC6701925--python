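"""Exact stochastic simulation of the three-species MukBEF model.

The model describes MukBEF cycling between a well-mixed cytosolic state w,
a mobile DNA-associated state u and a slowly diffusing clustered state v on
a 1-D compartment lattice representing the long cell axis.  u converts to v
at a basal rate alpha and cooperatively at a rate beta (a tri-molecular
channel, discretised as beta_hat*u*v*(v-1)); v reverts to u at gamma; u
unbinds to the cytosol at delta and w rebinds at epsilon, distributed over
compartments according to loading weights.  Differential diffusion of u and
v (D_u >> D_v) drives a Turing-type instability that condenses v into one
or more self-positioned clusters, while the well-mixed w state provides the
flux-balance signal that centres them.

Simulation is by the spatial Gillespie method: an exact realisation of the
reaction-diffusion master equation with reflecting boundaries, implemented
in a compiled kernel (:mod:`oriseg._ssa`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.optimize import brentq

from . import _ssa
from .params import (GrowthParams, InvalidParameterError, N_A, OriParams,
                     TuringParams)


class NumericalFailureError(RuntimeError):
    """A numerical sub-step (root finding, SSA consistency) failed."""


# ---------------------------------------------------------------------------
# molecule counts and homogeneous state
# ---------------------------------------------------------------------------

def total_molecules(C: float, V: float) -> int:
    """Number of molecules at concentration ``C`` (nM) in volume ``V`` (L).

    Rounds C*1e-9*V*N_A to the nearest integer (520 nM in a 1.25 fL birth
    volume gives 391 molecules).
    """
    if C < 0 or V <= 0:
        raise InvalidParameterError("require C >= 0 and V > 0")
    return int(round(C * 1e-9 * V * N_A))


@dataclass(frozen=True)
class HomogeneousState:
    """Spatially uniform steady state: real-valued root and integer rounding."""

    u: float
    v: float
    w: float
    u_int: int
    v_int: int
    w_int: int
    n_comp: int

    @property
    def total(self) -> int:
        return self.w_int + self.n_comp * (self.u_int + self.v_int)


def homogeneous_steady_state(params: TuringParams, N: int,
                             n_comp: Optional[int] = None,
                             V: Optional[float] = None) -> HomogeneousState:
    """Uniform root of the deterministic rate equations with total count N.

    Counts are per compartment for u and v, global for w, subject to the
    conservation law w + n_comp*(u + v) = N.  The integer configuration
    floors u and v per compartment and assigns the remainder to w.
    """
    if N <= 0:
        raise InvalidParameterError("N must be positive")
    if n_comp is None:
        n_comp = params.n_comp_at_length(params.L_birth)
    if V is None:
        V = params.volume_at_length(n_comp * params.h)
    bhat = params.beta_hat(V, n_comp)
    v2w = params.v_to_w
    n = n_comp
    a, g, d, e = params.alpha, params.gamma, params.delta, params.epsilon
    g_eff = g + (d if v2w else 0.0)

    def u_of(v):
        return g_eff * v / (a + bhat * v * v)

    def w_of(v):
        # from stationarity of the total nucleoid-bound pool
        return (n * d / e) * (u_of(v) + (v if v2w else 0.0))

    def residual(v):
        return w_of(v) + n * (u_of(v) + v) - N

    # bracket the root by sign scan over (0, N/n]
    vmax = N / n
    grid = np.linspace(1e-9 * vmax, vmax, 2000)
    res = np.array([residual(x) for x in grid])
    idx = np.nonzero(np.diff(np.sign(res)) != 0)[0]
    if len(idx) == 0:
        raise NumericalFailureError(
            f"no homogeneous root in (0, {vmax:.3g}]; residual range "
            f"[{res.min():.3g}, {res.max():.3g}]")
    v_star = brentq(residual, grid[idx[0]], grid[idx[0] + 1], xtol=1e-14)
    u_star = u_of(v_star)
    w_star = w_of(v_star)
    u_i = int(math.floor(u_star))
    v_i = int(math.floor(v_star))
    w_i = N - n * (u_i + v_i)
    return HomogeneousState(u_star, v_star, w_star, u_i, v_i, w_i, n)


# ---------------------------------------------------------------------------
# lattice state and propensities
# ---------------------------------------------------------------------------

@dataclass
class LatticeState:
    """Integer counts of u and v per compartment plus the cytosolic pool w."""

    n_comp: int
    u: np.ndarray
    v: np.ndarray
    w: int
    t: float = 0.0
    cell_length: float = 2.5

    def __post_init__(self):
        self.u = np.asarray(self.u, dtype=np.int64)
        self.v = np.asarray(self.v, dtype=np.int64)
        if len(self.u) != self.n_comp or len(self.v) != self.n_comp:
            raise InvalidParameterError("u, v must have length n_comp")
        if (self.u < 0).any() or (self.v < 0).any() or self.w < 0:
            raise InvalidParameterError("counts must be non-negative")

    @property
    def total(self) -> int:
        return int(self.w + self.u.sum() + self.v.sum())


def build_propensities(state: LatticeState, params: TuringParams,
                       loading_weights: Optional[np.ndarray] = None) -> dict:
    """Per-compartment event rates of the RDME (reference implementation).

    Returns a dict of arrays: ``a1`` (u->v, basal plus cooperative), ``a2``
    (v->u), ``a3`` (u->w), ``a4`` (w->u, split by the loading weights),
    ``u_left/u_right/v_left/v_right`` diffusion channels (reflecting
    boundaries) and the volume-rescaled cooperative constant ``beta_hat``.
    """
    n = state.n_comp
    if loading_weights is None:
        loading_weights = np.full(n, 1.0 / n)
    gsum = float(np.sum(loading_weights))
    if not math.isclose(gsum, 1.0, rel_tol=1e-9):
        raise InvalidParameterError("loading weights must sum to 1")
    V = params.volume_at_length(state.cell_length)
    bhat = params.beta_hat(V, n)
    u = state.u.astype(float)
    v = state.v.astype(float)
    a1 = params.alpha * u + bhat * u * v * (v - 1)
    a2 = params.gamma * v
    a3 = params.delta * u
    a4 = params.epsilon * state.w * np.asarray(loading_weights, dtype=float)
    du = params.D_u / params.h ** 2
    dv = params.D_v / params.h ** 2
    u_left = du * u
    u_left[0] = 0.0
    u_right = du * u
    u_right[-1] = 0.0
    v_left = dv * v
    v_left[0] = 0.0
    v_right = dv * v
    v_right[-1] = 0.0
    out = dict(a1=a1, a2=a2, a3=a3, a4=a4, u_left=u_left, u_right=u_right,
               v_left=v_left, v_right=v_right, beta_hat=bhat,
               c1=params.c1(V, n))
    if params.v_to_w:
        out["a5"] = params.delta * v
    return out


# ---------------------------------------------------------------------------
# linear stability of the homogeneous state
# ---------------------------------------------------------------------------

def linear_stability_check(params: TuringParams, n_comp: int) -> float:
    """Largest growth rate of spatial perturbation modes (s^-1).

    Linearises the deterministic equations about the homogeneous state.
    Because w is well-mixed, inhomogeneous modes couple only u and v; the
    dispersion relation is the largest real eigenvalue part of
    J - q^2 diag(D_u, D_v) over the discrete reflecting-boundary modes
    q_k = k*pi/L, k = 1..n_comp.  A positive value certifies the
    diffusion-driven instability on the configured domain.
    """
    L = n_comp * params.h
    V = params.volume_at_length(L)
    N = total_molecules(params.C, V)
    hs = homogeneous_steady_state(params, N, n_comp=n_comp, V=V)
    bhat = params.beta_hat(V, n_comp)
    a = params.alpha + bhat * hs.v ** 2
    b = 2.0 * bhat * hs.u * hs.v - params.gamma
    d_extra = params.delta if params.v_to_w else 0.0
    lam_max = -np.inf
    for k in range(1, n_comp + 1):
        q2 = (k * math.pi / L) ** 2
        J = np.array([
            [-a - params.delta - params.D_u * q2, -b],
            [a, b - d_extra - params.D_v * q2],
        ])
        lam = np.linalg.eigvals(J).real.max()
        lam_max = max(lam_max, lam)
    return float(lam_max)


# ---------------------------------------------------------------------------
# kymograph container
# ---------------------------------------------------------------------------

@dataclass
class Kymograph:
    """Readouts of a single simulation at a fixed interval (default 60 s).

    Times are seconds since the end of the equilibration period.  Per-readout
    compartment counts are stored as a list of arrays because the lattice
    grows during growth simulations.  ``ori_positions`` are micrometres from
    the left pole.
    """

    times: np.ndarray
    v_counts: list
    u_counts: list
    w: np.ndarray
    ori_positions: list
    cell_lengths: np.ndarray
    metadata: dict = field(default_factory=dict)

    @property
    def n_readouts(self) -> int:
        return len(self.times)

    def ori_tracks(self) -> np.ndarray:
        """(n_readouts, max_ori) array of ori positions, NaN before birth."""
        max_ori = max(len(p) for p in self.ori_positions) if self.ori_positions else 0
        out = np.full((self.n_readouts, max_ori), np.nan)
        for i, p in enumerate(self.ori_positions):
            out[i, :len(p)] = p
        return out

    def v_matrix(self) -> np.ndarray:
        """(n_readouts, max n_comp) matrix of v counts, NaN-padded."""
        m = max(len(c) for c in self.v_counts)
        out = np.full((self.n_readouts, m), np.nan)
        for i, c in enumerate(self.v_counts):
            out[i, :len(c)] = c
        return out

    def totals(self) -> np.ndarray:
        return np.array([self.w[i] + self.u_counts[i].sum() + self.v_counts[i].sum()
                         for i in range(self.n_readouts)], dtype=np.int64)

    def v_centroid(self) -> np.ndarray:
        """Centroid of the v profile (um from left pole) at each readout."""
        out = np.empty(self.n_readouts)
        h = self.metadata.get("h", 0.1)
        for i, c in enumerate(self.v_counts):
            x = (np.arange(len(c)) + 0.5) * h
            s = c.sum()
            out[i] = float((x * c).sum() / s) if s > 0 else np.nan
        return out

    def to_dataframe(self):
        import pandas as pd
        tracks = self.ori_tracks()
        data = {"t": self.times, "L": self.cell_lengths, "w": self.w}
        for k in range(tracks.shape[1]):
            data[f"x_ori{k + 1}"] = tracks[:, k]
        vmat = self.v_matrix()
        umat = np.full_like(vmat, np.nan)
        for i, c in enumerate(self.u_counts):
            umat[i, :len(c)] = c
        for j in range(vmat.shape[1]):
            data[f"v{j}"] = vmat[:, j]
        for j in range(umat.shape[1]):
            data[f"u{j}"] = umat[:, j]
        return pd.DataFrame(data)


# ---------------------------------------------------------------------------
# simulation driver
# ---------------------------------------------------------------------------

def _pack_params(params: TuringParams, ori_params: OriParams, V: float,
                 n_comp: int) -> np.ndarray:
    hs = ori_params.h_sub(params.h)
    P = np.zeros(14)
    P[_ssa.P_ALPHA] = params.alpha
    P[_ssa.P_BHAT] = params.beta_hat(V, n_comp)
    P[_ssa.P_GAMMA] = params.gamma
    P[_ssa.P_DELTA] = params.delta
    P[_ssa.P_EPS] = params.epsilon
    P[_ssa.P_DU] = params.D_u / params.h ** 2
    P[_ssa.P_DV] = params.D_v / params.h ** 2
    P[_ssa.P_V2W] = 1.0 if params.v_to_w else 0.0
    # bias per sub-step: alpha = mu * (v difference across one sub-step)/h,
    # i.e. the potential is mu times the linear density v/h of the clustered
    # species; the drift D*alpha/h_s = D*mu*(compartment difference)/h^2 is
    # then invariant under sub-compartment refinement
    P[_ssa.P_MUH] = ori_params.mu / (ori_params.n_sub * params.h)
    P[_ssa.P_DHS2] = ori_params.D_ori / hs ** 2
    P[_ssa.P_KREPF] = ori_params.k_rep * hs / (2.0 * ori_params.D_ori)
    P[_ssa.P_INVSIG] = 1.0 / ori_params.sigma_rep if ori_params.sigma_rep > 0 else 0.0
    P[_ssa.P_HS] = hs
    P[_ssa.P_RATIO] = ori_params.loading_ratio
    return P


class _SimState:
    """Mutable array bundle shared with the compiled kernel."""

    def __init__(self, params, ori_params, L, n_ori, ori_subs, n_comp_max):
        self.params = params
        self.ori_params = ori_params
        n_comp = params.n_comp_at_length(L)
        V = params.volume_at_length(L)
        N = total_molecules(params.C, V)
        hs0 = homogeneous_steady_state(params, N, n_comp=n_comp, V=V)
        self.u = np.zeros(n_comp_max, dtype=np.int64)
        self.v = np.zeros(n_comp_max, dtype=np.int64)
        self.u[:n_comp] = hs0.u_int
        self.v[:n_comp] = hs0.v_int
        self.prop = np.zeros((n_comp_max, _ssa.NCHAN))
        self.comp_sum = np.zeros(n_comp_max)
        self.gsum = np.zeros((n_comp_max + 7) // 8)
        self.g = np.zeros(n_comp_max)
        self.ori_pos = np.zeros(_ssa.MAX_ORI, dtype=np.int64)
        self.ori_comp = np.zeros(_ssa.MAX_ORI, dtype=np.int64)
        self.ori_sister = np.full(_ssa.MAX_ORI, -1, dtype=np.int64)
        self.ori_pos[:n_ori] = ori_subs
        self.oF = np.zeros(_ssa.MAX_ORI)
        self.oB = np.zeros(_ssa.MAX_ORI)
        self.SI = np.zeros(8, dtype=np.int64)
        self.SF = np.zeros(4)
        self.SI[0] = n_comp
        self.SI[1] = hs0.w_int
        self.SI[2] = n_ori
        self.P = _pack_params(params, ori_params, V, n_comp)
        self.rs = _ssa.make_rng_state(0)
        self.rebuild()

    @property
    def n_comp(self):
        return int(self.SI[0])

    @property
    def n_ori(self):
        return int(self.SI[2])

    @property
    def cell_length(self):
        return self.n_comp * self.params.h

    def rebuild(self):
        # jump-rate table over integer v differences (repulsion-free path)
        from .ori_coupling import _rate
        mu_h = self.P[_ssa.P_MUH]
        dhs2 = self.P[_ssa.P_DHS2]
        half = _ssa.OTAB_HALF
        self.otab = np.array([_rate(mu_h * k, dhs2)
                              for k in range(-half, half + 1)])
        _ssa.rebuild_all(self.u, self.v, self.prop, self.comp_sum, self.gsum,
                         self.g, self.ori_pos, self.ori_comp, self.ori_sister,
                         self.oF, self.oB, self.P, self.SI, self.SF,
                         self.ori_params.n_sub, self.otab)

    def run_until(self, t_stop):
        rc = _ssa.run_until(t_stop, self.u, self.v, self.prop, self.comp_sum,
                            self.gsum, self.g, self.ori_pos, self.ori_comp,
                            self.ori_sister, self.oF, self.oB, self.P,
                            self.SI, self.SF, self.ori_params.n_sub,
                            self.otab, self.rs)
        if rc == _ssa.STOP_ERROR:
            raise NumericalFailureError(
                "propensity sum vanished with molecules remaining")

    def ori_um(self):
        hs = self.ori_params.h_sub(self.params.h)
        return (self.ori_pos[:self.n_ori] + 0.5) * hs

    def duplicate(self, index):
        k = self.n_ori
        if k >= _ssa.MAX_ORI:
            raise RuntimeError("maximum ori count reached")
        self.ori_pos[k] = self.ori_pos[index]
        self.ori_sister[k] = index
        self.ori_sister[index] = k
        self.SI[2] = k + 1
        self.rebuild()

    def insert_compartment(self, slot):
        """Insert an empty compartment at ``slot`` and top up the cytosol."""
        n = self.n_comp
        self.u[slot + 1:n + 1] = self.u[slot:n]
        self.u[slot] = 0
        self.v[slot + 1:n + 1] = self.v[slot:n]
        self.v[slot] = 0
        nsub = self.ori_params.n_sub
        for k in range(self.n_ori):
            if self.ori_pos[k] >= slot * nsub:
                self.ori_pos[k] += nsub
        self.SI[0] = n + 1
        L_new = (n + 1) * self.params.h
        V_new = self.params.volume_at_length(L_new)
        target = total_molecules(self.params.C, V_new)
        self.SI[1] += target - self.total()
        self.P = _pack_params(self.params, self.ori_params, V_new, n + 1)
        self.rebuild()

    def total(self):
        n = self.n_comp
        return int(self.SI[1] + self.u[:n].sum() + self.v[:n].sum())


def _initial_ori_subs(mode, n_comp, n_sub, rng):
    nmax = n_comp * n_sub
    if mode == "midcell":
        return [nmax // 2]
    if mode == "quarters":
        return [nmax // 4, (3 * nmax) // 4]
    if mode == "random":
        return [int(rng.integers(0, nmax))]
    raise InvalidParameterError(f"unknown ori initialisation '{mode}'")


def simulate(params: TuringParams = None,
             ori_params: OriParams = None,
             growth_params: Optional[GrowthParams] = None,
             duration: float = 36000.0,
             readout: float = 60.0,
             seed: int = 0,
             equilibration: float = 1800.0,
             L: Optional[float] = None,
             ori_init="midcell",
             duplicate: Optional[bool] = None,
             record_u: bool = True) -> Kymograph:
    """Run one exact SSA realisation and return its kymograph.

    Parameters
    ----------
    params, ori_params : model parameters (defaults from the parameter tables).
    growth_params : if given, the cell grows exponentially from ``L_birth``
        to ``L_div`` by random compartment insertion, and each initial ori
        is assigned a duplication time from the length-triggered rule
        (disable with ``duplicate=False``).  ``duration`` is then capped at
        one doubling time.
    duration : simulated seconds after equilibration.
    readout : readout interval in seconds (60 s to match 1-min imaging).
    equilibration : warm-up seconds before the first readout (default 30 min).
    L : initial cell length in um (default birth length).
    ori_init : 'midcell', 'quarters', 'random', or an explicit sequence of
        positions in um.
    """
    if params is None:
        params = TuringParams()
    if ori_params is None:
        ori_params = OriParams()
    if not duration >= readout > 0:
        raise InvalidParameterError("require duration >= readout > 0")
    if L is None:
        L = growth_params.L_birth if growth_params else params.L_birth

    ss = np.random.SeedSequence(seed)
    kernel_seed, py_seed = (int(s) % (2 ** 31) for s in
                            ss.generate_state(2, dtype=np.uint64))
    rng = np.random.default_rng(py_seed)

    n_comp0 = params.n_comp_at_length(L)
    n_sub = ori_params.n_sub
    if isinstance(ori_init, str):
        ori_subs = _initial_ori_subs(ori_init, n_comp0, n_sub, rng)
    else:
        hs = ori_params.h_sub(params.h)
        ori_subs = [min(n_comp0 * n_sub - 1, max(0, int(x / hs)))
                    for x in ori_init]
    n_comp_max = n_comp0 + (growth_params.n_insertions if growth_params else 0)
    st = _SimState(params, ori_params, L, len(ori_subs), ori_subs, n_comp_max)
    st.rs = _ssa.make_rng_state(kernel_seed)

    # event schedule: (time_s, priority, kind, payload); kind handled in order
    events = []
    t_end = equilibration + duration
    if growth_params is not None:
        from .cell_growth import growth_schedule
        for t_min in growth_schedule(growth_params):
            t_ev = equilibration + 60.0 * t_min
            if t_ev <= t_end:
                events.append((t_ev, 0, "grow", None))
        if duplicate is None:
            duplicate = True
        if duplicate:
            from .ori_coupling import sample_duplication_time
            for k in range(st.n_ori):
                t_min = sample_duplication_time(growth_params, ori_params, rng)
                events.append((equilibration + 60.0 * t_min, 1, "dup", k))
    n_read = int(math.floor(duration / readout + 1e-9)) + 1
    for i in range(n_read):
        events.append((equilibration + i * readout, 2, "read", None))
    events.sort(key=lambda e: (e[0], e[1]))

    times, v_counts, u_counts, w_arr, ori_pos_list, lengths = \
        [], [], [], [], [], []
    dup_log, grow_log = [], []
    for t_ev, _, kind, payload in events:
        st.run_until(t_ev)
        if kind == "grow":
            slot = int(rng.integers(0, st.n_comp + 1))
            st.insert_compartment(slot)
            grow_log.append({"t": t_ev - equilibration, "slot": slot})
        elif kind == "dup":
            st.duplicate(payload)
            dup_log.append({"t": t_ev - equilibration,
                            "x": float(st.ori_um()[payload])})
        else:
            times.append(t_ev - equilibration)
            n = st.n_comp
            v_counts.append(st.v[:n].copy())
            u_counts.append(st.u[:n].copy() if record_u else np.zeros(0, dtype=np.int64))
            w_arr.append(int(st.SI[1]))
            ori_pos_list.append(np.array(st.ori_um()))
            lengths.append(st.cell_length)

    meta = {
        "seed": seed,
        "h": params.h,
        "readout": readout,
        "equilibration": equilibration,
        "params": params.to_dict(),
        "ori_params": ori_params.to_dict(),
        "growth_params": growth_params.to_dict() if growth_params else None,
        "duplications": dup_log,
        "growth_events": grow_log,
    }
    return Kymograph(np.array(times), v_counts, u_counts,
                     np.array(w_arr, dtype=np.int64), ori_pos_list,
                     np.array(lengths), meta)
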