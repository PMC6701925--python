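"""Experiment orchestration: configuration, seeds, scenarios, file output.

An :class:`ExperimentSpec` names one of the canned scenarios and carries the
model parameters; :func:`run_experiment` executes the replicates with
counter-derived per-replicate seeds (reproducible regardless of execution
order) and writes plain tabular outputs plus a JSON metadata record:

* ``tracks.csv`` — run_id, t (s), L (um), ori positions and, for fixed-length
  scenarios, detected MukBEF focus positions (um from the left pole);
* ``kymographs.csv`` — per readout, per compartment v counts (long format);
* ``summary.json`` — scenario-appropriate statistics (OU fit, partitioning
  accuracy, crossings, ...);
* ``metadata.json`` — seed, full parameter set, package version, per-replicate
  status.

Configuration files are YAML with sections mirroring the parameter tables
(``turing``, ``ori``, ``growth``, ``polymer``, ``experiment``); unknown keys
are rejected by name.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .model_core import Kymograph, simulate
from .params import (GrowthParams, InvalidParameterError, ORI_GROWTH,
                     OriParams, TuringParams)
from .polymer_looping import PolymerConfig, run_polymer
from .trajectory_analysis import (Track, crossing_count, detect_foci, fit_ou,
                                  partitioning_accuracy, segregation_velocity,
                                  stepwise_velocity_profile)

SCENARIOS = ("fixed-length-1ori", "fixed-length-2ori", "growing-cell",
             "multifork", "polymer-single", "polymer-double", "analysis-only")


@dataclass
class ExperimentSpec:
    """A named scenario plus parameters, replicate count and seed policy."""

    scenario: str = "fixed-length-1ori"
    turing: TuringParams = field(default_factory=TuringParams)
    ori: Optional[OriParams] = None
    growth: GrowthParams = field(default_factory=GrowthParams)
    polymer: PolymerConfig = field(default_factory=PolymerConfig)
    replicates: int = 10
    seed: int = 0
    duration_min: float = 600.0
    readout_s: float = 60.0
    equilibration_min: float = 30.0
    tracks_path: Optional[str] = None   # analysis-only input

    def __post_init__(self):
        if self.scenario not in SCENARIOS:
            raise InvalidParameterError(
                f"unknown scenario '{self.scenario}'; choose from {SCENARIOS}")
        if self.replicates < 0:
            raise InvalidParameterError("replicates must be >= 0")
        if self.ori is None:
            self.ori = (ORI_GROWTH if self.scenario in
                        ("growing-cell", "multifork") else OriParams())

    def replicate_seed(self, rep: int) -> int:
        """Counter-based per-replicate seed derived from the master seed."""
        ss = np.random.SeedSequence(entropy=self.seed, spawn_key=(rep,))
        return int(ss.generate_state(1, dtype=np.uint64)[0] % (2 ** 31))

    def param_hash(self) -> str:
        blob = json.dumps(_spec_to_dict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _spec_to_dict(spec: ExperimentSpec) -> dict:
    d = {
        "scenario": spec.scenario,
        "turing": spec.turing.to_dict(),
        "ori": spec.ori.to_dict(),
        "growth": spec.growth.to_dict(),
        "polymer": dataclasses.asdict(spec.polymer),
        "experiment": {
            "replicates": spec.replicates,
            "seed": spec.seed,
            "duration_min": spec.duration_min,
            "readout_s": spec.readout_s,
            "equilibration_min": spec.equilibration_min,
            "tracks_path": spec.tracks_path,
        },
    }
    d["polymer"]["box"] = list(spec.polymer.box)
    return d


def serialise_config(spec: ExperimentSpec) -> str:
    return yaml.safe_dump(_spec_to_dict(spec), sort_keys=True)


def parse_config(path) -> ExperimentSpec:
    """Load an ExperimentSpec from YAML; unknown keys are rejected by name.

    An empty file yields the full parameter-table defaults.  The round trip
    ``parse -> serialise -> parse`` is the identity.
    """
    text = Path(path).read_text()
    data = yaml.safe_load(text) or {}
    if not isinstance(data, dict):
        raise InvalidParameterError("config root must be a mapping")
    known = {"scenario", "turing", "ori", "growth", "polymer", "experiment"}
    for key in data:
        if key not in known:
            raise InvalidParameterError(f"unknown config section '{key}'")

    def build(cls, section, **extra):
        raw = dict(data.get(section) or {})
        fields = {f.name for f in dataclasses.fields(cls)}
        for key, val in raw.items():
            if key not in fields:
                raise InvalidParameterError(
                    f"unknown key '{section}.{key}'")
            if isinstance(val, str):
                raise InvalidParameterError(
                    f"malformed numeric value for '{section}.{key}': {val!r}")
        if "box" in raw:
            raw["box"] = tuple(raw["box"])
        if "dup_range" in raw:
            raw["dup_range"] = tuple(raw["dup_range"])
        return cls(**{**extra, **raw})

    exp = dict(data.get("experiment") or {})
    exp_known = {"replicates", "seed", "duration_min", "readout_s",
                 "equilibration_min", "tracks_path"}
    for key in exp:
        if key not in exp_known:
            raise InvalidParameterError(f"unknown key 'experiment.{key}'")
    scenario = data.get("scenario", "fixed-length-1ori")
    spec = ExperimentSpec(
        scenario=scenario,
        turing=build(TuringParams, "turing"),
        ori=build(OriParams, "ori") if "ori" in data else None,
        growth=build(GrowthParams, "growth"),
        polymer=build(PolymerConfig, "polymer"),
        **exp,
    )
    return spec


# ---------------------------------------------------------------------------
# scenario execution
# ---------------------------------------------------------------------------

def _run_replicate(spec: ExperimentSpec, rep: int) -> Kymograph:
    seed = spec.replicate_seed(rep)
    dur = spec.duration_min * 60.0
    eq = spec.equilibration_min * 60.0
    if spec.scenario == "fixed-length-1ori":
        return simulate(spec.turing, spec.ori, duration=dur,
                        readout=spec.readout_s, seed=seed, equilibration=eq,
                        L=spec.turing.L_birth, ori_init="midcell")
    if spec.scenario == "fixed-length-2ori":
        return simulate(spec.turing, spec.ori, duration=dur,
                        readout=spec.readout_s, seed=seed, equilibration=eq,
                        L=2.0 * spec.turing.L_birth, ori_init="quarters")
    if spec.scenario == "growing-cell":
        return simulate(spec.turing, spec.ori, spec.growth,
                        duration=min(dur, spec.growth.T_double * 60.0),
                        readout=spec.readout_s, seed=seed, equilibration=eq,
                        ori_init="midcell")
    if spec.scenario == "multifork":
        # higher copy number; two oris start at the quarter positions and
        # each duplicates independently under the length-triggered rule
        turing = spec.turing.replace(C=1000.0)
        return simulate(turing, spec.ori, spec.growth,
                        duration=min(dur, spec.growth.T_double * 60.0),
                        readout=spec.readout_s, seed=seed, equilibration=eq,
                        ori_init="quarters")
    raise InvalidParameterError(f"not a stochastic scenario: {spec.scenario}")


def _tracks_frame(kymos: List[Kymograph], n_foci: int, h: float) -> pd.DataFrame:
    rows = []
    for rid, k in enumerate(kymos):
        tracks = k.ori_tracks()
        for i, t in enumerate(k.times):
            row = {"run_id": rid, "t": t, "L": k.cell_lengths[i]}
            for j in range(tracks.shape[1]):
                row[f"x_ori{j + 1}"] = tracks[i, j]
            if n_foci:
                pos, found = detect_foci(k.v_counts[i], n_foci, h=h)
                for j in range(n_foci):
                    row[f"x_focus{j + 1}"] = (pos[j] if j < len(pos)
                                              else np.nan)
            rows.append(row)
    return pd.DataFrame(rows)


def _kymo_frame(kymos: List[Kymograph]) -> pd.DataFrame:
    rows = []
    for rid, k in enumerate(kymos):
        for i, t in enumerate(k.times):
            v = k.v_counts[i]
            for c in range(len(v)):
                rows.append((rid, t, c, int(v[c])))
    return pd.DataFrame(rows, columns=["run_id", "t", "compartment", "v"])


def _summarise(spec: ExperimentSpec, kymos: List[Kymograph],
               tracks: pd.DataFrame) -> dict:
    out = {"scenario": spec.scenario, "replicates": len(kymos)}
    if not kymos:
        return out
    dt = spec.readout_s
    if spec.scenario == "fixed-length-1ori":
        tr = [Track(k.times, k.ori_tracks()[:, 0], k.cell_lengths)
              for k in kymos]
        try:
            fit = fit_ou(stepwise_velocity_profile(tr))
            out["ou_fit"] = {"D_a": fit.D_a, "d_a": fit.d_a, "tau": fit.tau,
                             "f_over_kT": fit.f_over_kT, "valid": fit.valid}
        except InvalidParameterError as exc:
            out["ou_fit"] = {"error": str(exc)}
    if spec.scenario in ("fixed-length-2ori", "growing-cell", "multifork"):
        x1, x2, L, crossings, seg_rates = [], [], [], [], []
        for k in kymos:
            tr = k.ori_tracks()
            if tr.shape[1] < 2 or np.isnan(tr[-1, 1]):
                continue
            x1.append(tr[-1, 0])
            x2.append(tr[-1, 1])
            L.append(k.cell_lengths[-1])
            both = ~np.isnan(tr[:, 0]) & ~np.isnan(tr[:, 1])
            crossings.append(crossing_count(tr[both, 0], tr[both, 1]))
            T2 = (spec.growth.T_double * 60.0
                  if spec.scenario != "fixed-length-2ori" else None)
            if both.sum() >= 2:
                seg_rates.append(float(np.mean(segregation_velocity(
                    tr[both, 0], tr[both, 1], dt, T2))))
        if x1:
            out["partitioning_accuracy"] = partitioning_accuracy(
                np.array(x1), np.array(x2), np.array(L))
            out["mean_crossings"] = float(np.mean(crossings))
            out["mean_segregation_velocity"] = float(np.mean(seg_rates))
            out["n_scored"] = len(x1)
    return out


def run_experiment(spec: ExperimentSpec, outdir) -> dict:
    """Run all replicates of a scenario and write outputs to ``outdir``.

    Replicate failures are recorded and do not abort the run; the returned
    metadata lists per-replicate status and the summary only covers
    successful replicates.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    meta = {
        "version": __version__,
        "seed": spec.seed,
        "param_hash": spec.param_hash(),
        "spec": _spec_to_dict(spec),
        "replicate_status": [],
        "failures": 0,
    }
    if spec.scenario in ("polymer-single", "polymer-double"):
        cfg = spec.polymer
        if spec.scenario == "polymer-double" and not cfg.double:
            cfg = dataclasses.replace(cfg, double=True)
        cfg = dataclasses.replace(cfg, seed=spec.seed,
                                  n_trajectories=spec.replicates or
                                  cfg.n_trajectories)
        trajs = run_polymer(cfg)
        rows = []
        for tid, z in enumerate(trajs):
            for i in range(z.shape[0]):
                row = {"trajectory_id": tid, "mcs": (i + 1) * cfg.readout,
                       "z_rel_ori": z[i, 0]}
                if z.shape[1] > 1:
                    row["z_rel_ori2"] = z[i, 1]
                rows.append(row)
        df = pd.DataFrame(rows)
        df.to_csv(outdir / "polymer_tracks.csv", index=False)
        meta["replicate_status"] = ["ok"] * len(trajs)
        summary = {"scenario": spec.scenario, "trajectories": len(trajs),
                   "mean_abs_z_rel": float(np.nanmean(np.abs(
                       df["z_rel_ori"]))) if len(df) else None}
    elif spec.scenario == "analysis-only":
        if not spec.tracks_path:
            raise InvalidParameterError("analysis-only needs tracks_path")
        df = pd.read_csv(spec.tracks_path)
        from .synthetic_data import frame_to_tracks
        tr = frame_to_tracks(df)
        fit = fit_ou(stepwise_velocity_profile(tr))
        summary = {"scenario": spec.scenario,
                   "ou_fit": {"D_a": fit.D_a, "d_a": fit.d_a, "tau": fit.tau,
                              "f_over_kT": fit.f_over_kT,
                              "valid": fit.valid}}
    else:
        kymos = []
        for rep in range(spec.replicates):
            try:
                kymos.append(_run_replicate(spec, rep))
                meta["replicate_status"].append("ok")
            except Exception as exc:   # record, continue
                meta["replicate_status"].append(f"failed: {exc}")
                meta["failures"] += 1
        n_foci = {"fixed-length-1ori": 1, "fixed-length-2ori": 2}.get(
            spec.scenario, 0)
        tracks = _tracks_frame(kymos, n_foci, spec.turing.h)
        tracks.to_csv(outdir / "tracks.csv", index=False)
        _kymo_frame(kymos).to_csv(outdir / "kymographs.csv", index=False)
        summary = _summarise(spec, kymos, tracks)
    (outdir / "summary.json").write_text(json.dumps(summary, indent=2,
                                                    sort_keys=True))
    (outdir / "metadata.json").write_text(json.dumps(meta, indent=2,
                                                     sort_keys=True))
    return summary
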