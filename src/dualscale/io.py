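"""Serialization: ensemble bundles (HDF5) and report tables (CSV/JSON)."""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np

from .ensemble import EnsembleMember, EnsembleSpec
from .model import DynamicState, IntrinsicState
from .sensing import SensorFilters, SensorTargets

__all__ = ["save_ensemble", "load_ensemble", "write_report"]


def save_ensemble(path, ensemble, spec: EnsembleSpec) -> None:
    """One HDF5 bundle: per-model intrinsic state, sensor targets, period,
    settled dynamic state, plus the generating spec for provenance."""
    with h5py.File(path, "w") as f:
        f.attrs["n_models"] = spec.n_models
        f.attrs["seed"] = spec.seed
        f.attrs["offset_range"] = spec.offset_range
        f.attrs["gmax_jitter"] = spec.gmax_jitter
        f.attrs["period_tolerance"] = spec.period_tolerance
        f.attrs["settle_duration"] = spec.settle_duration
        for m in ensemble:
            grp = f.create_group(m.model_id)
            grp.attrs["index"] = m.index
            grp.attrs["period"] = m.period
            grp.attrs["leak_g"] = m.intrinsic.leak_g
            grp.create_dataset("gmax", data=m.intrinsic.gmax)
            grp.create_dataset("half_shifts", data=m.intrinsic.half_shifts)
            grp.create_dataset("targets", data=m.targets.as_array())
            if m.settled_state is not None:
                st = m.settled_state
                grp.create_dataset("state_V", data=[st.V])
                grp.create_dataset("state_gates", data=st.gates)
                grp.create_dataset("state_Ca", data=[st.Ca])
                grp.create_dataset("state_filters",
                                   data=st.filters.as_array())


def load_ensemble(path):
    """(list of EnsembleMember, EnsembleSpec) from a bundle file."""
    members = []
    with h5py.File(path, "r") as f:
        spec = EnsembleSpec(
            n_models=int(f.attrs["n_models"]), seed=int(f.attrs["seed"]),
            offset_range=float(f.attrs["offset_range"]),
            gmax_jitter=float(f.attrs["gmax_jitter"]),
            period_tolerance=float(f.attrs["period_tolerance"]),
            settle_duration=float(f.attrs["settle_duration"]))
        for model_id in sorted(f.keys()):
            grp = f[model_id]
            intrinsic = IntrinsicState(
                gmax=grp["gmax"][...], half_shifts=grp["half_shifts"][...],
                leak_g=float(grp.attrs["leak_g"]))
            targets = SensorTargets(*grp["targets"][...])
            state = None
            if "state_V" in grp:
                state = DynamicState(
                    V=float(grp["state_V"][0]), gates=grp["state_gates"][...],
                    Ca=float(grp["state_Ca"][0]),
                    filters=SensorFilters.from_array(grp["state_filters"][...]))
            members.append(EnsembleMember(
                model_id=model_id, index=int(grp.attrs["index"]),
                intrinsic=intrinsic, targets=targets,
                period=float(grp.attrs["period"]), settled_state=state))
    return members, spec


def write_report(outdir, report: dict) -> None:
    """Write each report entry's tables as CSV plus a JSON summary."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    summary = {}
    for key, entry in report.items():
        tag = key.replace(":", "_")
        for name in ("latency", "classification", "conductance_trajectories",
                     "halfshift_trajectories"):
            if name in entry and len(entry[name]):
                entry[name].to_csv(outdir / f"{tag}_{name}.csv", index=False)
        for name in ("latency_stats", "conductance_norm_stats",
                     "halfshift_norm_stats"):
            if name in entry:
                entry[name].to_frame().to_csv(
                    outdir / f"{tag}_{name}.csv", index=False)
        summary[key] = {
            "counts": entry.get("counts", {}),
            "latency_medians": {
                str(k): (None if np.isnan(v) else float(v))
                for k, v in entry.get(
                    "latency_medians", {}).items()},
            "latency_missing": entry.get("latency_missing"),
        }
    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2)
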