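"""Shared fixtures: simulation ensembles reused across test modules.

The heavier SSA ensembles are session-scoped so that property tests and the
acceptance checks draw on the same runs instead of re-simulating.
"""

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from oriseg import model_core as mc
from oriseg.params import OriParams
from oriseg.trajectory_analysis import Track

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


def ori_track(kymo, index=0):
    """Track of one ori from a kymograph (NaN-free prefix trimmed)."""
    x = kymo.ori_tracks()[:, index]
    ok = ~np.isnan(x)
    return Track(kymo.times[ok], x[ok], kymo.cell_lengths[ok])


@pytest.fixture(scope="session")
def midcell_kymos():
    """Four 2.5 um fixed-length runs (single ori, 150 min each) at the
    production single-cell configuration: growth-fit ori parameters with
    6x preferential loading."""
    op = OriParams(D_ori=5.1e-5, mu=0.052, loading_ratio=6.0)
    return [mc.simulate(ori_params=op, duration=150 * 60, seed=7000 + s)
            for s in range(4)]


@pytest.fixture(scope="session")
def ratio_kymos():
    """5 um two-ori runs (150 min) for loading ratios 1, 2, 4, 6 and 16.

    Matched seeds across ratios: replicate r of every ratio uses the same
    seed, isolating the loading-ratio effect.
    """
    ratios = (1.0, 2.0, 4.0, 6.0, 16.0)
    out = {}
    for ratio in ratios:
        out[ratio] = [
            mc.simulate(ori_params=OriParams(loading_ratio=ratio),
                        duration=150 * 60, seed=7700 + r, L=5.0,
                        ori_init="quarters")
            for r in range(3)
        ]
    return out


@pytest.fixture(scope="session")
def ou_track_ensemble():
    """100 exact OU tracks at the synthetic-data reference parameters."""
    from oriseg.synthetic_data import OUTrackSpec, gen_ou_tracks
    spec = OUTrackSpec(D_a=5e-5, tau=1000.0, home=1.25, delta_t=60.0,
                       n_tracks=100, n_steps=600, L=2.5, seed=42)
    return spec, gen_ou_tracks(spec)


#: desk-scale polymer geometry used across the polymer behaviour tests:
#: a 48-monomer ring in a 10 x 10 x 40 box (monomer-to-volume ratio ~10%)
POLYMER_SMALL = dict(box=(10, 10, 40), n_monomers=48, sd_rel=0.1,
                     loop_lifetime=1000, readout=250)


@pytest.fixture(scope="session")
def polymer_density_runs():
    """Ori z-densities without looping, with flat looping and with a
    centred looping profile (6 trajectories each, first fifth discarded)."""
    from oriseg.polymer_looping import PolymerConfig, run_polymer
    out = {}
    for key, p_max, uniform in (("none", 0.0, False),
                                ("uniform", 0.1, True),
                                ("centred", 0.1, False)):
        cfg = PolymerConfig(p_max=p_max, uniform_looping=uniform,
                            n_readouts=1200, n_trajectories=6, seed=61,
                            **POLYMER_SMALL)
        out[key] = [t[len(t) // 5:, 0] for t in run_polymer(cfg)]
    return out
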