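"""Confined ring-polymer Monte Carlo with dynamic position-dependent looping.

The chromosome is a self-avoiding ring polymer in the bond-fluctuation
representation, confined to a cuboid with a 4:1 aspect ratio (default
22 x 22 x 88 lattice sites holding 464 monomers, a monomer-to-volume ratio
of 464*8/42592 ~ 9%).  One designated monomer (*ori*) can form transient
loops (bridges) with distal monomers; the probability of forming a loop
depends on the *ori*'s relative position along the long axis through a
Gaussian profile emulating the MukBEF concentration: a single centred
Gaussian (single-chromosome mode) or the sum of two Gaussians at the
quarter positions (two-chromosome mode).  Loops live for a fixed number of
Monte-Carlo steps.  A spatial gradient in looping probability rectifies the
*ori*'s elastic fluctuations into directed motion towards the looping
maximum.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional

import numpy as np

from . import _bfm, _ssa
from .params import InvalidParameterError


@dataclass(frozen=True)
class PolymerConfig:
    """Geometry, looping profile and sampling plan for polymer runs.

    Defaults are the full production scale (one 464-monomer ring in a
    22 x 22 x 88 box, readouts every 5e4 MCS); tests and desk-scale studies
    pass smaller boxes/chains and shorter readouts.  ``sd_rel`` is the
    profile width as a fraction of the long axis (0.1, i.e. 8.8 lattice
    units for the default box).
    """

    box: tuple = (22, 22, 88)
    n_monomers: int = 464
    double: bool = False            # two rings of n_monomers/2 each
    p_max: float = 0.02
    sd_rel: float = 0.1
    loop_lifetime: int = 10_000     # MCS
    readout: int = 50_000           # MCS between recorded conformations
    n_readouts: int = 100
    n_trajectories: int = 10
    max_loops: int = 1
    uniform_looping: bool = False   # position-independent p = p_max
    seed: int = 0

    def __post_init__(self):
        X, Y, Z = self.box
        if min(X, Y, Z) < 4:
            raise InvalidParameterError("box too small")
        if self.double and self.n_monomers % 2:
            raise InvalidParameterError("double mode needs an even monomer count")
        if not 0 <= self.p_max <= 1:
            raise InvalidParameterError("p_max must be a probability")

    @property
    def centres(self) -> np.ndarray:
        if self.double:
            return np.array([-0.25, 0.25])
        return np.array([0.0])


def looping_probability(x_rel: float, config: PolymerConfig) -> float:
    """Loop-formation probability at relative long-axis position x_rel.

    Single mode: p_max * exp(-x_rel^2/(2 sd^2)); double mode: the sum of the
    two quarter-position Gaussians, capped at 1.  With
    ``uniform_looping`` the profile is flat at p_max.
    """
    if not -0.5 - 1e-9 <= x_rel <= 0.5 + 1e-9:
        raise InvalidParameterError("x_rel must be in [-0.5, 0.5]")
    if config.uniform_looping:
        return min(config.p_max, 1.0)
    inv2sd2 = 1.0 / (2.0 * config.sd_rel ** 2)
    return float(_bfm.loop_probability(x_rel, config.centres, inv2sd2,
                                       config.p_max))


def _serpentine(n_cols: int, n_rows: int, y0: int, z0: int) -> list:
    """Open serpentine path over an n_cols x n_rows grid of spacing 2."""
    path = []
    for c in range(n_cols):
        rows = range(n_rows) if c % 2 == 0 else range(n_rows - 1, -1, -1)
        for r in rows:
            path.append((y0 + 2 * c, z0 + 2 * r))
    return path


def _ring_two_layers(n: int, box, x0: int, z_offset: int = 0) -> np.ndarray:
    """Closed ring of n monomers: a serpentine in layer x0 mirrored in x0+2.

    All bonds have length 2; cubes on the spacing-2 grid are disjoint, so
    the conformation is always valid.
    """
    X, Y, Z = box
    half = n // 2
    # pick a columns x rows factorisation of the layer that fits the box,
    # preferring the most compact (fewest rows along z)
    n_cols = 0
    for c in range(min((Y - 2) // 2 + 1, half), 0, -1):
        if half % c == 0 and 2 * (half // c - 1) <= Z - 2:
            n_cols = c
            break
    if n_cols == 0 or x0 < 0 or x0 + 3 > X - 1:
        raise InvalidParameterError("ring does not fit the box")
    n_rows = half // n_cols
    z0 = (Z - 2 - 2 * (n_rows - 1)) // 2 + z_offset
    z0 = max(0, min(Z - 2 - 2 * (n_rows - 1), z0))
    y0 = (Y - 2 - 2 * (n_cols - 1)) // 2
    path = _serpentine(n_cols, n_rows, y0, z0)
    pos = np.empty((n, 3), dtype=np.int64)
    for i, (y, z) in enumerate(path):
        pos[i] = (x0, y, z)
    for i, (y, z) in enumerate(reversed(path)):
        pos[half + i] = (x0 + 2, y, z)
    return pos


class Polymer:
    """A confined ring-polymer system with loop state and an MC driver."""

    def __init__(self, config: PolymerConfig, seed: Optional[int] = None,
                 z_offset: int = 0):
        self.config = config
        X, Y, Z = config.box
        if config.double:
            half = config.n_monomers // 2
            posA = _ring_two_layers(half, config.box, x0=(X - 2) // 2 - 3,
                                    z_offset=z_offset)
            posB = _ring_two_layers(half, config.box, x0=(X - 2) // 2 + 1,
                                    z_offset=z_offset)
            self.pos = np.vstack([posA, posB])
            self.ring_next = np.empty(config.n_monomers, dtype=np.int64)
            self.ring_prev = np.empty(config.n_monomers, dtype=np.int64)
            for s, e in ((0, half), (half, config.n_monomers)):
                for i in range(s, e):
                    self.ring_next[i] = s + (i - s + 1) % (e - s)
                    self.ring_prev[i] = s + (i - s - 1) % (e - s)
            # oris: monomer of each ring nearest the long-axis centre
            zc = (Z - 2) / 2
            self.ori_idx = np.array(
                [s + int(np.argmin(np.abs(self.pos[s:e, 2] - zc)))
                 for s, e in ((0, half), (half, config.n_monomers))],
                dtype=np.int64)
        else:
            self.pos = _ring_two_layers(config.n_monomers, config.box,
                                        x0=(X - 2) // 2 - 1,
                                        z_offset=z_offset)
            n = config.n_monomers
            self.ring_next = (np.arange(n, dtype=np.int64) + 1) % n
            self.ring_prev = (np.arange(n, dtype=np.int64) - 1) % n
            self.ori_idx = np.array([0], dtype=np.int64)
        self.occ, ok = _bfm.build_occupancy(self.pos, X, Y, Z)
        if not ok or not _bfm.check_conformation(self.pos, self.ring_next,
                                                 X, Y, Z):
            raise InvalidParameterError("initial conformation invalid")
        n_ori = len(self.ori_idx)
        self.loop_partner = np.full((n_ori, config.max_loops), -1,
                                    dtype=np.int64)
        self.loop_expiry = np.zeros((n_ori, config.max_loops), dtype=np.int64)
        self.partner_of = np.full(config.n_monomers, -1, dtype=np.int64)
        self.rs = _ssa.make_rng_state(config.seed if seed is None else seed)
        self.now = 0
        self._cand = np.empty(config.n_monomers, dtype=np.int64)

    def _profile(self):
        if self.config.uniform_looping:
            # flat profile: a single 'Gaussian' of effectively infinite width
            return np.array([0.0]), 0.0
        return self.config.centres, 1.0 / (2.0 * self.config.sd_rel ** 2)

    def set_ori_index(self, indices):
        self.ori_idx = np.asarray(indices, dtype=np.int64)
        n_ori = len(self.ori_idx)
        self.loop_partner = np.full((n_ori, self.config.max_loops), -1,
                                    dtype=np.int64)
        self.loop_expiry = np.zeros((n_ori, self.config.max_loops),
                                    dtype=np.int64)
        self.partner_of[:] = -1

    def mc_step(self) -> int:
        """One MCS (N move attempts) followed by the loop update."""
        X, Y, Z = self.config.box
        acc = _bfm.sweep(self.pos, self.occ, self.ring_next, self.ring_prev,
                         self.partner_of, self.ori_idx, self.loop_partner,
                         X, Y, Z, self.rs)
        self.now += 1
        centres, inv2sd2 = self._profile()
        _bfm.update_loops(self.now, self.pos, self.ring_next, self.ring_prev,
                          self.partner_of, self.ori_idx, self.loop_partner,
                          self.loop_expiry, centres, inv2sd2,
                          self.config.p_max, self.config.loop_lifetime, Z,
                          self.rs, self._cand)
        return acc

    def run(self, n_readouts: Optional[int] = None,
            readout: Optional[int] = None) -> np.ndarray:
        """Advance the system, returning ori relative z, shape
        (n_readouts, n_ori)."""
        cfg = self.config
        n_read = cfg.n_readouts if n_readouts is None else n_readouts
        rd = cfg.readout if readout is None else readout
        X, Y, Z = cfg.box
        out = np.empty((n_read, len(self.ori_idx)))
        centres, inv2sd2 = self._profile()
        _bfm.run_traj(self.pos, self.occ, self.ring_next, self.ring_prev,
                      self.partner_of, self.ori_idx, self.loop_partner,
                      self.loop_expiry, X, Y, Z, centres, inv2sd2, cfg.p_max,
                      cfg.loop_lifetime, rd, n_read, self.rs, out,
                      self._cand)
        self.now += n_read * rd
        return out

    def ori_z_rel(self) -> np.ndarray:
        Z = self.config.box[2]
        return (self.pos[self.ori_idx, 2] + 1.0) / Z - 0.5

    def active_loops(self) -> list:
        out = []
        for o in range(self.loop_partner.shape[0]):
            for l in range(self.loop_partner.shape[1]):
                if self.loop_partner[o, l] >= 0:
                    out.append((int(self.ori_idx[o]),
                                int(self.loop_partner[o, l]),
                                int(self.loop_expiry[o, l])))
        return out


def run_polymer(config: PolymerConfig) -> List[np.ndarray]:
    """Independent trajectories of ori relative z positions.

    Single mode varies the initial ring placement along the long axis to
    cover it uniformly; double mode always starts with the two overlapping
    rings centred (oris at mid-box).  Returns one (n_readouts, n_ori) array
    per trajectory.
    """
    ss = np.random.SeedSequence(config.seed)
    seeds = [int(s) % (2 ** 31) for s in
             ss.generate_state(config.n_trajectories, dtype=np.uint64)]
    Z = config.box[2]
    out = []
    for i, sd in enumerate(seeds):
        if config.double or config.n_trajectories == 1:
            zoff = 0
        else:
            span = Z // 3
            zoff = int(round(-span / 2 + span * i /
                             max(1, config.n_trajectories - 1)))
        poly = Polymer(config, seed=sd, z_offset=zoff)
        out.append(poly.run())
    return out
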