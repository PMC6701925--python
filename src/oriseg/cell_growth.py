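"""Exponential cell growth by stochastic compartment insertion.

The cell length grows exponentially with doubling time T_double; on the
lattice this is realised by inserting one empty compartment of width h at a
uniformly random slot (poles included) every time the continuous length has
grown by h.  Molecules are added through the cytosolic pool so that the
total count tracks C * V(t) * N_A, with fractional remainders carried
rather than discarded; existing compartment contents are never touched and
*ori* positions keep their compartment, so the relative position x/L is
unchanged in expectation by an insertion.
"""

from __future__ import annotations

from typing import List

import numpy as np

from .model_core import LatticeState, total_molecules
from .ori_coupling import OriState
from .params import GrowthParams, InvalidParameterError, TuringParams


def growth_schedule(growth: GrowthParams) -> List[float]:
    """Times (minutes since birth) of the compartment insertions.

    t_k = T_double * log2((L_birth + k*h) / L_birth) for k = 1..n_insertions;
    strictly increasing with strictly decreasing intervals, ending exactly at
    T_double when L_div = 2*L_birth.
    """
    return [growth.length_to_time(growth.L_birth + k * growth.h)
            for k in range(1, growth.n_insertions + 1)]


def insert_compartment(state: LatticeState, ori: OriState, rng,
                       params: TuringParams = None,
                       slot: int = None) -> tuple:
    """Insert one empty compartment; returns (new_state, new_ori, slot).

    The insertion slot is uniform on the n_comp+1 possibilities (both poles
    included).  Compartment contents shift right of the slot; *ori*
    sub-lattice indices right of the slot shift by n_sub.  The cytosolic
    count w is increased so the new total equals
    ``total_molecules(C, V_new)`` (nearest-integer tracking of the real
    target, i.e. remainder-carrying).
    """
    if params is None:
        params = TuringParams()
    n = state.n_comp
    if slot is None:
        slot = int(rng.integers(0, n + 1))
    if not 0 <= slot <= n:
        raise InvalidParameterError("slot out of range")
    u = np.insert(state.u, slot, 0)
    v = np.insert(state.v, slot, 0)
    L_new = (n + 1) * params.h
    target = total_molecules(params.C, params.volume_at_length(L_new))
    w_new = state.w + (target - state.total)
    if w_new < 0:
        raise InvalidParameterError("cytosolic pool cannot absorb shrinkage")
    new_state = LatticeState(n + 1, u, v, int(w_new), state.t, L_new)
    positions = [p + ori.n_sub if p >= slot * ori.n_sub else p
                 for p in ori.positions]
    new_ori = OriState(positions, n + 1, ori.n_sub, list(ori.sisters))
    return new_state, new_ori, slot
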