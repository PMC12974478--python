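"""Seeded generation of degenerate bursting model neurons.

The reference burster is a calibrated seven-conductance configuration that
bursts under baseline conditions and enters depolarization block when the
potassium and leak reversal potentials are stepped to their high-potassium
values.  Ensemble members are drawn around it: uniform initial
half-(in)activation offsets per curve plus relative jitter on every maximal
conductance, then filtered for stable spontaneous bursting and for a burst
period within tolerance of the candidate-set average.  Each accepted member
stores its own calibrated sensor targets, so the whole population is a pure
function of the ensemble specification.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .burst import burst_statistics, classify_window, detect_spike_peaks
from .channels import N_CHANNELS, N_CURVES
from .model import IntrinsicState, simulate
from .protocol import (BASELINE_E_K, BASELINE_E_LEAK, Epoch,
                       PerturbationSchedule)
from .sensing import SensorTargets, calibrate_targets

__all__ = [
    "REFERENCE_GMAX", "REFERENCE_LEAK_G", "EnsembleSpec", "EnsembleMember",
    "reference_model", "sample_candidate", "period_filter",
    "generate_ensemble", "settle_and_calibrate",
]

#: μS of membrane conductance per mS/cm² at the reference membrane area
_AREA_FACTOR = 0.628

#: calibrated reference densities (mS/cm²), channel order Na, CaT, CaS, H,
#: Kd, KCa, A.  Chosen so the baseline attractor is regular bursting while
#: the high-potassium environment puts the naive model into depolarization
#: block with a multi-millivolt escape margin.
_REFERENCE_DENSITIES = (50.0, 5.0, 6.0, 0.05, 80.0, 0.75, 45.0)
_REFERENCE_LEAK_DENSITY = 0.05

REFERENCE_GMAX = np.array(_REFERENCE_DENSITIES) * _AREA_FACTOR
REFERENCE_LEAK_G = _REFERENCE_LEAK_DENSITY * _AREA_FACTOR

SETTLE_DURATION_S = 600.0
CALIBRATION_WINDOW_S = 120.0


class GenerationError(RuntimeError):
    """Raised when too few candidates survive the acceptance filters."""


@dataclass(frozen=True)
class EnsembleSpec:
    n_models: int = 20
    seed: int = 0
    #: half-width (mV) of the uniform initial half-shift offsets.  ±2 mV
    #: keeps most candidates inside the naive vulnerability class (blocked by
    #: high potassium until the slow process acts) while still producing
    #: distinct voltage-dependence profiles and the occasional preadapted
    #: model, mirroring the published population proportions.
    offset_range: float = 2.0
    gmax_jitter: float = 0.2  # relative, uniform half-width
    period_tolerance: float = 0.2  # fraction of the candidate-set mean
    settle_duration: float = SETTLE_DURATION_S  # s

    def __post_init__(self):
        if self.n_models < 1:
            raise ValueError("n_models must be >= 1")
        if self.period_tolerance <= 0:
            raise ValueError("period_tolerance must be positive")


@dataclass(frozen=True)
class EnsembleMember:
    model_id: str
    index: int  # draw index within the seeded stream
    intrinsic: IntrinsicState
    targets: SensorTargets
    period: float  # s, baseline burst period after settling
    settled_state: object = field(repr=False, default=None)  # DynamicState


def reference_model() -> IntrinsicState:
    return IntrinsicState(gmax=REFERENCE_GMAX.copy(),
                          half_shifts=np.zeros(N_CURVES),
                          leak_g=REFERENCE_LEAK_G)


def _baseline_schedule(duration: float) -> PerturbationSchedule:
    return PerturbationSchedule(epochs=(
        Epoch("baseline", 0.0, duration, BASELINE_E_K, BASELINE_E_LEAK),))


def sample_candidate(spec: EnsembleSpec, index: int) -> IntrinsicState:
    """Deterministic candidate for (seed, index): half-shift offsets drawn
    uniformly in ±offset_range, conductances jittered by ±gmax_jitter."""
    if index < 0:
        raise ValueError("index must be non-negative")
    rng = np.random.default_rng((spec.seed, index))
    shifts = rng.uniform(-spec.offset_range, spec.offset_range, N_CURVES)
    jitter = rng.uniform(-spec.gmax_jitter, spec.gmax_jitter, N_CHANNELS)
    return IntrinsicState(gmax=REFERENCE_GMAX * (1.0 + jitter),
                         half_shifts=shifts, leak_g=REFERENCE_LEAK_G)


def period_filter(periods, tolerance: float):
    """Indices whose period lies within ``tolerance`` of the set mean,
    re-evaluated iteratively until the accepted set is stable."""
    periods = np.asarray(periods, dtype=float)
    if periods.size == 0:
        raise ValueError("period_filter requires at least one period")
    if np.any(periods <= 0):
        raise ValueError("periods must be positive")
    accepted = np.arange(periods.size)
    while accepted.size:
        mean = periods[accepted].mean()
        keep = accepted[np.abs(periods[accepted] - mean)
                        <= tolerance * mean]
        if keep.size == accepted.size:
            break
        accepted = keep
    return list(accepted)


def settle_and_calibrate(intrinsic: IntrinsicState,
                         settle_duration: float = SETTLE_DURATION_S,
                         dt: float = 0.1):
    """Settle a model at baseline and calibrate its sensor targets.

    Returns (targets, period, trace) or None if the model does not burst
    stably or shows too few burst periods in the calibration window.
    """
    trace = simulate(intrinsic, _baseline_schedule(settle_duration), dt=dt)
    t0 = trace.t_v[-1] - CALIBRATION_WINDOW_S
    mask = trace.t_v >= t0
    if classify_window(trace.V[mask], trace.t_v[mask]) != "bursting":
        return None
    try:
        targets = calibrate_targets(trace, window_s=CALIBRATION_WINDOW_S)
    except ValueError:
        return None
    train = detect_spike_peaks(trace.V[mask], trace.t_v[mask])
    period, _, _ = burst_statistics(train)
    if period is None:
        return None
    return targets, float(period), trace


def generate_ensemble(spec: EnsembleSpec, dt: float = 0.1,
                      progress=None) -> list[EnsembleMember]:
    """Draw seeded candidates until ``n_models`` pass stability and the
    iterative period filter; fully reproducible from the spec."""
    stable: list[EnsembleMember] = []
    draws = 0
    rate_check = max(10 * spec.n_models, 20)
    max_draws = max(100 * spec.n_models, 200)
    while draws < max_draws:
        index = draws
        draws += 1
        candidate = sample_candidate(spec, index)
        result = settle_and_calibrate(candidate, spec.settle_duration, dt=dt)
        if progress is not None:
            progress(index, result is not None)
        if result is None:
            continue
        targets, period, trace = result
        stable.append(EnsembleMember(
            model_id=f"m{index:03d}", index=index, intrinsic=candidate,
            targets=targets, period=period,
            settled_state=trace.final_state))
        if len(stable) >= spec.n_models:
            accepted = period_filter([m.period for m in stable],
                                     spec.period_tolerance)
            if len(accepted) >= spec.n_models:
                return [stable[i] for i in accepted[:spec.n_models]]
        if draws == rate_check and len(stable) * 100 < draws:
            raise GenerationError(
                f"acceptance rate below 1%: {len(stable)}/{draws} "
                "candidates produced stable bursting")
    raise GenerationError(
        f"could not assemble {spec.n_models} models from {draws} draws "
        f"({len(stable)} stable bursters)")
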