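"""End-to-end experiment families over a seeded ensemble.

Each experiment simulates every ensemble member under one regulation
variant and the repeated high-potassium schedule, then measures per-model
burst-onset latencies, wash-window activity classes, and the parameter-space
trajectory summaries in both conductance space (7-D) and half-shift space
(11-D).  Reconfiguration experiments rebuild a model from the end state of a
source run (keeping either the final conductances or the final half-shifts)
and re-expose it to the identical schedule.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd

from .burst import classify_window, detect_spike_peaks, time_to_first_burst
from .ensemble import EnsembleMember
from .geometry import (DISPLACEMENT_LABELS, extract_snapshots,
                       trajectory_summary)
from .model import IntegrationError, IntrinsicState, simulate
from .protocol import PerturbationSchedule, build_schedule
from .regulation import VARIANTS, make_regulation_config
from .stats import dunn_bonferroni

__all__ = [
    "PROFILES", "ModelResult", "ExperimentResult", "run_model",
    "run_protocol_experiment", "reconfigure_model", "aggregate_and_report",
]

#: named schedule profiles: full-scale (the 220-min protocol) and a
#: scaled-down CI profile with 5-min epochs for fast qualitative checks.
PROFILES = {
    "full": dict(lead_s=600.0, n_cycles=3, pert_s=1800.0, wash_s=1800.0,
                 tail_s=1800.0),
    "ci": dict(lead_s=120.0, n_cycles=3, pert_s=300.0, wash_s=300.0,
               tail_s=120.0),
}

#: length of the classification window at the end of each wash (s)
WASH_WINDOW_S = 300.0


@dataclass
class ModelResult:
    model_id: str
    latencies: list  # per perturbation, s or None
    pert_end_classes: list  # activity class in the last window of each pert
    wash_classes: list  # activity class in the last window of each wash
    g_summary: Optional[dict]  # conductance-space trajectory summary
    shift_summary: Optional[dict]  # half-shift-space trajectory summary
    max_abs_shift: float  # mV over all recorded samples
    initial_intrinsic: IntrinsicState = field(repr=False, default=None)
    final_intrinsic: IntrinsicState = field(repr=False, default=None)
    error: Optional[str] = None


@dataclass
class ExperimentResult:
    variant: str
    profile: str
    schedule: PerturbationSchedule = field(repr=False, default=None)
    models: list = field(default_factory=list)
    manifest: dict = field(default_factory=dict)

    def model(self, model_id: str) -> ModelResult:
        for m in self.models:
            if m.model_id == model_id:
                return m
        raise KeyError(model_id)


def _wash_windows(schedule: PerturbationSchedule, profile: str):
    """(start, end) classification window at the end of each nominal wash.

    The final wash epoch is extended by the tail; its window is anchored at
    the end of the nominal wash duration, not the end of the tail.
    """
    wash_s = PROFILES.get(profile, PROFILES["full"])["wash_s"]
    # final 5 min of a full-scale wash; proportionally scaled (but at least
    # one classification window) for shorter profiles
    w = min(WASH_WINDOW_S, max(61.0, 0.2 * wash_s))
    windows = []
    for ep in schedule.wash_epochs:
        nominal_end = min(ep.start + wash_s, ep.end)
        windows.append((nominal_end - w, nominal_end))
    return windows


def run_model(member: EnsembleMember, variant: str,
              schedule: PerturbationSchedule, dt: float = 0.1,
              profile: str = "full") -> ModelResult:
    """Simulate one model under a regulation variant and measure it."""
    cfg = make_regulation_config(
        variant, targets=member.targets,
        shift_reference=member.intrinsic.half_shifts)
    initial = member.settled_state
    try:
        trace = simulate(member.intrinsic, schedule, regulation=cfg,
                         targets=member.targets, dt=dt, initial=initial)
    except IntegrationError as exc:
        return ModelResult(
            model_id=member.model_id, latencies=[], pert_end_classes=[],
            wash_classes=[], g_summary=None, shift_summary=None,
            max_abs_shift=float("nan"), error=str(exc))

    train = detect_spike_peaks(trace.V, trace.t_v)
    latencies, pert_end = [], []
    for ep in schedule.perturbation_epochs:
        latencies.append(time_to_first_burst(train, ep.start, ep.end))
        m = (trace.t_v >= ep.end - 61.0) & (trace.t_v < ep.end)
        pert_end.append(classify_window(trace.V[m], trace.t_v[m]))
    wash_classes = []
    for lo, hi in _wash_windows(schedule, profile):
        m = (trace.t_v >= lo) & (trace.t_v < hi)
        wash_classes.append(classify_window(trace.V[m], trace.t_v[m]))

    g_summary = shift_summary = None
    if len(schedule.perturbation_epochs) == 3:
        g_series = extract_snapshots(trace.t_p, trace.gmax, schedule)
        s_series = extract_snapshots(trace.t_p, trace.half_shifts, schedule)
        g_summary = trajectory_summary(g_series)
        shift_summary = trajectory_summary(s_series)
        g_summary["snapshots"] = g_series.points
        shift_summary["snapshots"] = s_series.points

    return ModelResult(
        model_id=member.model_id, latencies=latencies,
        pert_end_classes=pert_end, wash_classes=wash_classes,
        g_summary=g_summary, shift_summary=shift_summary,
        max_abs_shift=float(np.max(np.abs(trace.half_shifts))),
        initial_intrinsic=trace.intrinsic_initial,
        final_intrinsic=trace.intrinsic_final)


def run_protocol_experiment(ensemble, variant: str,
                            schedule: PerturbationSchedule | None = None,
                            dt: float = 0.1, profile: str = "full",
                            progress=None) -> ExperimentResult:
    """Run one regulation variant over every ensemble member.

    Integration failures are recorded on the per-model result and listed in
    the manifest; the run continues with the remaining models.
    """
    if variant not in VARIANTS:
        raise ValueError(f"unknown variant {variant!r}")
    if schedule is None:
        schedule = build_schedule(**PROFILES[profile])
    models = []
    for member in ensemble:
        result = run_model(member, variant, schedule, dt=dt, profile=profile)
        models.append(result)
        if progress is not None:
            progress(member.model_id, result.error)
    manifest = {
        "variant": variant,
        "profile": profile,
        "dt_ms": dt,
        "epochs": schedule.to_manifest(),
        "model_ids": [m.model_id for m in models],
        "failures": {m.model_id: m.error for m in models if m.error},
    }
    return ExperimentResult(variant=variant, profile=profile,
                            schedule=schedule, models=models,
                            manifest=manifest)


def reconfigure_model(member: EnsembleMember, source: ExperimentResult,
                      keep: str) -> EnsembleMember:
    """Rebuild a model from a source run's end state.

    ``keep="final_gmax"`` keeps the run-final maximal conductances and
    resets the half-shifts to the member's initial values;
    ``keep="final_halfshifts"`` keeps the run-final half-shifts and restores
    the initial conductances.  Sensor targets are unchanged.
    """
    result = source.model(member.model_id)
    if result.final_intrinsic is None:
        raise ValueError(
            f"source run holds no final state for {member.model_id}")
    if keep == "final_gmax":
        intrinsic = IntrinsicState(
            gmax=result.final_intrinsic.gmax.copy(),
            half_shifts=member.intrinsic.half_shifts.copy(),
            leak_g=member.intrinsic.leak_g)
    elif keep == "final_halfshifts":
        intrinsic = IntrinsicState(
            gmax=member.intrinsic.gmax.copy(),
            half_shifts=result.final_intrinsic.half_shifts.copy(),
            leak_g=member.intrinsic.leak_g)
    else:
        raise ValueError("keep must be 'final_gmax' or 'final_halfshifts'")
    return replace(member, intrinsic=intrinsic,
                   model_id=f"{member.model_id}:{keep}",
                   settled_state=None)


def latency_table(result: ExperimentResult) -> pd.DataFrame:
    rows = []
    for m in result.models:
        for k, lat in enumerate(m.latencies, start=1):
            rows.append({"model_id": m.model_id, "perturbation_index": k,
                         "latency_s": np.nan if lat is None else lat})
    return pd.DataFrame(rows)


def classification_table(result: ExperimentResult) -> pd.DataFrame:
    rows = []
    for m in result.models:
        for k, cls in enumerate(m.wash_classes, start=1):
            rows.append({"model_id": m.model_id, "window": f"wash{k}",
                         "activity": cls})
        for k, cls in enumerate(m.pert_end_classes, start=1):
            rows.append({"model_id": m.model_id, "window": f"pert{k}_end",
                         "activity": cls})
    return pd.DataFrame(rows)


def trajectory_table(result: ExperimentResult, space: str) -> pd.DataFrame:
    key = "g_summary" if space == "conductance" else "shift_summary"
    rows = []
    for m in result.models:
        summary = getattr(m, key)
        if summary is None:
            continue
        row = {"model_id": m.model_id, "radius": summary["radius"],
               "outside_distance": summary["outside_distance"],
               "center_distance": summary["center_distance"],
               "angle_pert_wash_pert": summary["angle_pert_wash_pert"],
               "angle_wash_pert_wash": summary["angle_wash_pert_wash"]}
        for label in DISPLACEMENT_LABELS:
            row[label] = summary["norms"][label]
        rows.append(row)
    return pd.DataFrame(rows)


def aggregate_and_report(results) -> dict:
    """Summary bundle over one or more experiment results.

    Emits the latency table with per-perturbation medians and the
    Kruskal-Wallis/Dunn comparison, displacement-norm tables with their
    comparisons, per-model sphere and angle tables, and headline counts.
    Models without spikes in an epoch are excluded from the latency
    statistics, with the exclusion count recorded.
    """
    if not results:
        raise ValueError("aggregate_and_report requires at least one result")
    report = {}
    for result in results:
        lat = latency_table(result)
        entry = {"latency": lat, "classification": classification_table(result)}
        if not lat.empty:
            groups, labels = [], []
            for k, sub in lat.groupby("perturbation_index"):
                vals = sub["latency_s"].dropna().to_numpy()
                if vals.size:
                    groups.append(vals)
                    labels.append(f"pert{k}")
            entry["latency_medians"] = lat.groupby("perturbation_index")[
                "latency_s"].median()
            entry["latency_missing"] = int(lat["latency_s"].isna().sum())
            if len(groups) >= 2:
                entry["latency_stats"] = dunn_bonferroni(groups, labels)
        for space in ("conductance", "halfshift"):
            tab = trajectory_table(
                result, "conductance" if space == "conductance" else "shift")
            entry[f"{space}_trajectories"] = tab
            if not tab.empty:
                norm_groups = [tab[label].to_numpy()
                               for label in DISPLACEMENT_LABELS]
                entry[f"{space}_norm_stats"] = dunn_bonferroni(
                    norm_groups, list(DISPLACEMENT_LABELS))
        gt = entry["conductance_trajectories"]
        counts = {}
        if not gt.empty:
            counts["n_models"] = int(len(gt))
            counts["n_outside_positive"] = int(
                (gt["outside_distance"] > 0).sum())
            counts["n_center_beyond_radius"] = int(
                (gt["center_distance"] > 2 * gt["radius"]).sum())
        if not lat.empty:
            wide = lat.pivot(index="model_id", columns="perturbation_index",
                             values="latency_s")
            if set(wide.columns) >= {1, 2, 3}:
                improved = (wide[1] > wide[2]) & (wide[1] > wide[3])
                counts["n_latency_improved"] = int(improved.fillna(False).sum())
        wash = [m for m in result.models if not m.error]
        counts["n_all_wash_bursting"] = sum(
            1 for m in wash
            if m.wash_classes and all(c == "bursting" for c in m.wash_classes))
        entry["counts"] = counts
        report[f"{result.variant}:{result.profile}"] = entry
    return report
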