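"""Coupling of *ori* particles to the self-organised MukBEF gradient.

The *ori* is a point particle on a sub-compartment lattice (``n_sub`` odd
sub-compartments per reaction compartment).  Its hop rates follow the
Wang-Peskin-Elston discretisation of drift-diffusion in a potential

    F = (D/h_s^2) * a / (1 - exp(-a)),   B = (D/h_s^2) * a / (exp(a) - 1),

where a is the dimensionless potential drop towards the target
sub-compartment, here ``a = mu * (v_target - v_here) / h`` with v the
linearly interpolated count of the clustered MukBEF species and h the
reaction-compartment width (the potential is mu times the linear density
v/h, making the drift independent of the sub-lattice refinement).  The
scheme
satisfies detailed balance and the exact drift identity
``(F - B) * h_s = D * a / h_s``, which is used to translate the entropic
sister-repulsion speed into an additional jump-rate bias.

The pure functions here are the reference implementation; the SSA kernel
(:mod:`oriseg._ssa`) inlines identical formulas.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .params import GrowthParams, InvalidParameterError, OriParams


def interpolate_v(v: np.ndarray, j: int, n_sub: int) -> float:
    """v at sub-compartment j, piecewise-linear between compartment centres.

    Compartment i's centre sits at sub-index ``i*n_sub + (n_sub-1)//2``.
    Beyond the outermost centres the profile is extrapolated as constant.
    """
    v = np.asarray(v, dtype=float)
    n_comp = len(v)
    half = (n_sub - 1) // 2
    nmax = n_comp * n_sub
    if not 0 <= j < nmax:
        raise InvalidParameterError("sub-index out of range")
    if j <= half:
        return float(v[0])
    if j >= (n_comp - 1) * n_sub + half:
        return float(v[-1])
    i = (j - half) // n_sub
    frac = (j - (i * n_sub + half)) / n_sub
    return float(v[i] + frac * (v[i + 1] - v[i]))


def biased_rates(alpha: float, D_ori: float, h_s: float) -> tuple:
    """Wang-Peskin-Elston rates for a dimensionless potential drop ``alpha``.

    F = (D/h_s^2) * alpha / (1 - exp(-alpha)) towards the drop and
    B = (D/h_s^2) * alpha / (exp(alpha) - 1) away from it; both reduce to
    D/h_s^2 at alpha = 0 and are overflow-safe up to |alpha| = 700.
    """
    if h_s <= 0:
        raise InvalidParameterError("h_s must be positive")
    d = D_ori / h_s ** 2
    return _rate(alpha, d), _rate(-alpha, d)


def jump_rates(v_here: float, v_next: float, D_ori: float, mu: float,
               h_s: float, h: float = 0.1) -> tuple:
    """Forward and backward jump rates (s^-1) across one sub-compartment.

    The bias is ``alpha = mu * (v_next - v_here) / h`` with v the
    interpolated clustered-MukBEF count at the two sub-compartments and h
    the reaction-compartment width: the potential experienced by the ori is
    mu times the linear density v/h of the clustered species, so alpha is
    dimensionless and the physical drift D*alpha/h_s equals
    D*mu*(compartment difference)/h^2 independently of the sub-compartment
    refinement.  ``F`` is the rate for the hop towards ``v_next``; ``B``
    the rate of the reverse hop from the neighbour's perspective.  Both
    reduce to ``D_ori/h_s^2`` for a flat profile.
    """
    return biased_rates(mu * (v_next - v_here) / h, D_ori, h_s)


def _rate(a: float, d: float) -> float:
    if a > 700.0:
        return d * a
    if a < -700.0:
        return 0.0
    if abs(a) < 1e-9:
        return d * (1.0 + 0.5 * a)
    return d * a / (1.0 - math.exp(-a))


def loading_weights(n_comp: int, ori_compartments, ratio: float) -> np.ndarray:
    """Normalised per-compartment loading weights g (sum 1).

    Compartments containing at least one *ori* receive weight ratio/Z, all
    others 1/Z, so the total loading rate epsilon*w is unchanged.  A
    compartment holding two *ori*s counts once.
    """
    if n_comp < 1:
        raise InvalidParameterError("empty domain")
    if ratio < 1:
        raise InvalidParameterError("ratio must be >= 1")
    occ = set(int(i) for i in ori_compartments)
    if any(i < 0 or i >= n_comp for i in occ):
        raise InvalidParameterError("ori compartment out of range")
    g = np.ones(n_comp)
    for i in occ:
        g[i] = ratio
    return g / g.sum()


def repulsion_speed(d: float, k_rep: float, sigma_rep: float) -> float:
    """Separation speed v_s = k*d*exp(-d^2/(2 sigma^2)) between sisters (um/s).

    This is the overdamped velocity derived from a Gaussian entropic
    potential in the sister separation d; it vanishes at contact and decays
    beyond the range sigma, with a maximum exactly at d = sigma.
    """
    if d < 0:
        raise InvalidParameterError("separation must be non-negative")
    if sigma_rep <= 0:
        return 0.0
    x = d / sigma_rep
    return k_rep * d * math.exp(-0.5 * x * x)


def repulsion_bias(d: float, k_rep: float, sigma_rep: float, D_ori: float,
                   h_s: float) -> float:
    """Jump-rate bias a_rep per *ori* equivalent to half the separation speed.

    Each sister carries half of v_s, directed away from the other; using the
    drift identity of the jump scheme, speed v corresponds to a bias
    a = v*h_s/D, hence a_rep = v_s*h_s/(2*D_ori).  The caller adds it to the
    gradient bias with the sign of the away-from-sister direction.
    """
    return repulsion_speed(d, k_rep, sigma_rep) * h_s / (2.0 * D_ori)


def sample_duplication_length(ori_params: OriParams, rng) -> float:
    """Cell length (um) at which ori duplicates: truncated normal by rejection."""
    lo, hi = ori_params.dup_range
    mean, sd = ori_params.dup_mean_length, ori_params.dup_sd_length
    if sd == 0:
        return min(max(mean, lo), hi)
    for _ in range(100000):
        x = rng.normal(mean, sd)
        if lo <= x <= hi:
            return float(x)
    raise RuntimeError("truncated-normal rejection sampling failed")


def sample_duplication_time(growth: GrowthParams, ori_params: OriParams,
                            rng) -> float:
    """Duplication time in minutes since birth under exponential growth.

    A duplication length L_d is drawn from the truncated normal (mean 3 um,
    CV 0.16, range [2.5, 5] um by default) and mapped through
    t = T_double * log2(L_d / L_birth).
    """
    lo, hi = ori_params.dup_range
    if lo < growth.L_birth - 1e-9 or hi > growth.L_div + 1e-9:
        raise InvalidParameterError("dup_range must lie within [L_birth, L_div]")
    L_d = sample_duplication_length(ori_params, rng)
    return growth.length_to_time(L_d)


@dataclass
class OriState:
    """Positions of 1-4 *ori* particles as 0-based sub-lattice indices.

    The continuous position of index j is (j + 0.5) * h_s from the left
    pole, with h_s = h / n_sub.  ``sisters[k]`` is the index of ori k's
    duplication partner (or -1).
    """

    positions: list
    n_comp: int
    n_sub: int
    sisters: list = field(default_factory=list)

    def __post_init__(self):
        nmax = self.n_comp * self.n_sub
        if not 1 <= len(self.positions) <= 4:
            raise InvalidParameterError("ori count must be between 1 and 4")
        if any(not 0 <= p < nmax for p in self.positions):
            raise InvalidParameterError("ori sub-index out of range")
        if not self.sisters:
            self.sisters = [-1] * len(self.positions)

    @property
    def count(self) -> int:
        return len(self.positions)

    def positions_um(self, h: float) -> np.ndarray:
        hs = h / self.n_sub
        return (np.asarray(self.positions) + 0.5) * hs

    def compartments(self) -> list:
        return [p // self.n_sub for p in self.positions]


def duplicate_ori(state: OriState, index: int = 0) -> OriState:
    """Duplicate ori ``index``: the sister appears in the same sub-compartment.

    Both copies subsequently move independently.  Raises if the ori already
    has a sister (one duplication per event).
    """
    if state.sisters[index] >= 0:
        raise RuntimeError("ori already duplicated")
    if state.count >= 4:
        raise RuntimeError("maximum ori count reached")
    positions = list(state.positions) + [state.positions[index]]
    sisters = list(state.sisters) + [index]
    sisters[index] = len(positions) - 1
    return OriState(positions, state.n_comp, state.n_sub, sisters)
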