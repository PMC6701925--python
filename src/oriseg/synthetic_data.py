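"""Generators of synthetic locus tracks with known ground truth.

These replace microscopy-derived inputs for testing the analysis stage.
Tracks are exact samples of an Ornstein-Uhlenbeck process around a home
position using the closed-form transition density

    x(t+dt) | x(t) ~ Normal(home + (x(t)-home) e^{-dt/tau},
                            D_a tau (1 - e^{-2 dt/tau})),

with the initial point drawn from the stationary law Normal(home, D_a tau).
The generator therefore has no discretisation error at any readout
interval; reflection at the cell boundaries is applied only for the rare
step that would exit the domain (a warning is raised when the stationary
spread makes the walls relevant, because that breaks the OU assumptions an
analysis may rely on).  Localisation error can be emulated by a single
optional additive Gaussian term.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import List

import numpy as np
import pandas as pd

from .params import InvalidParameterError
from .trajectory_analysis import Track


@dataclass(frozen=True)
class OUTrackSpec:
    """Specification of an ensemble of OU tracks.

    D_a (um^2/s) and tau (s) are the apparent diffusion constant and
    relaxation time; ``home`` is the attractor position (um from the left
    pole of a cell of length L).
    """

    D_a: float = 5.4e-5
    tau: float = 1000.0
    home: float = 1.25
    delta_t: float = 60.0
    n_tracks: int = 100
    n_steps: int = 600
    L: float = 2.5
    seed: int = 0
    noise_sd: float = 0.0  # optional localisation error, um

    def __post_init__(self):
        for name in ("D_a", "tau", "delta_t", "L"):
            if getattr(self, name) <= 0:
                raise InvalidParameterError(f"{name} must be positive")
        if not 0 < self.home < self.L:
            raise InvalidParameterError("home must lie inside (0, L)")
        if self.n_tracks < 1 or self.n_steps < 1:
            raise InvalidParameterError("need at least one track and step")


def gen_ou_tracks(spec: OUTrackSpec, rng=None) -> List[Track]:
    """Exact OU track ensemble per ``spec`` (bit-reproducible given the seed)."""
    rng = np.random.default_rng(spec.seed if rng is None else rng)
    sd_stat = np.sqrt(spec.D_a * spec.tau)
    if sd_stat > spec.L / 4.0:
        warnings.warn("stationary sd exceeds L/4: wall reflections will "
                      "distort the OU statistics")
    lam = np.exp(-spec.delta_t / spec.tau)
    sd_step = np.sqrt(spec.D_a * spec.tau * (1.0 - lam ** 2))
    times = np.arange(spec.n_steps) * spec.delta_t
    tracks = []
    for _ in range(spec.n_tracks):
        x = np.empty(spec.n_steps)
        x[0] = spec.home + sd_stat * rng.standard_normal()
        x[0] = _reflect(x[0], spec.L)
        steps = rng.standard_normal(spec.n_steps - 1)
        for i in range(1, spec.n_steps):
            xi = spec.home + (x[i - 1] - spec.home) * lam + sd_step * steps[i - 1]
            x[i] = _reflect(xi, spec.L)
        if spec.noise_sd > 0:
            x = np.clip(x + spec.noise_sd * rng.standard_normal(spec.n_steps),
                        0.0, spec.L)
        tracks.append(Track(times, x, np.full(spec.n_steps, spec.L)))
    return tracks


def _reflect(x: float, L: float) -> float:
    # fold back into [0, L]; at most a few folds are ever needed
    while x < 0.0 or x > L:
        if x < 0.0:
            x = -x
        if x > L:
            x = 2.0 * L - x
    return x


def gen_colocalised_pair(spec: OUTrackSpec, coupling: float,
                         rng=None) -> tuple:
    """A track and a colocalised partner offset by N(0, coupling^2) noise.

    Positive control for colocalisation analyses: at coupling = 0 the
    partner is identical; the mean separation is coupling*sqrt(2/pi)
    (folded normal).
    """
    if coupling < 0:
        raise InvalidParameterError("coupling must be non-negative")
    rng = np.random.default_rng(spec.seed if rng is None else rng)
    (track_a,) = gen_ou_tracks(spec.__class__(**{**spec.__dict__,
                                                 "n_tracks": 1}), rng)
    offset = coupling * rng.standard_normal(len(track_a.positions))
    pos_b = np.clip(track_a.positions + offset, 0.0, spec.L)
    track_b = Track(track_a.times, pos_b, track_a.cell_lengths)
    return track_a, track_b


def gen_independent_positions(marginal_a, marginal_b, n: int,
                              seed: int = 0) -> tuple:
    """Independent paired draws from two marginals (negative control).

    Each marginal is either an array of values to resample from or a
    callable ``f(rng, n)`` returning n draws.
    """
    if n < 1:
        raise InvalidParameterError("n must be >= 1")
    rng = np.random.default_rng(seed)

    def draw(marg):
        if callable(marg):
            return np.asarray(marg(rng, n), dtype=float)
        arr = np.asarray(marg, dtype=float)
        return rng.choice(arr, size=n, replace=True)

    return draw(marginal_a), draw(marginal_b)


def tracks_to_frame(tracks: List[Track], run_ids=None) -> pd.DataFrame:
    """Serialise tracks to the CSV schema consumed by the analysis stage
    (columns: run_id, t, x_ori1, L)."""
    frames = []
    for i, tr in enumerate(tracks):
        frames.append(pd.DataFrame({
            "run_id": (run_ids[i] if run_ids is not None else i),
            "t": tr.times,
            "x_ori1": tr.positions,
            "L": tr.cell_lengths,
        }))
    return pd.concat(frames, ignore_index=True)


def frame_to_tracks(df: pd.DataFrame, column: str = "x_ori1") -> List[Track]:
    """Inverse of :func:`tracks_to_frame` for any ori/focus column."""
    out = []
    for _, grp in df.groupby("run_id", sort=True):
        grp = grp.sort_values("t")
        out.append(Track(grp["t"].to_numpy(), grp[column].to_numpy(),
                         grp["L"].to_numpy()))
    return out
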