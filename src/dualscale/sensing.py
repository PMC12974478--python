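"""Calcium-signal decomposition and the homeostatic error signal.

Three first-order low-pass filters with increasing time constants track the
intracellular calcium concentration: a fast one that follows spike-driven
calcium entry, a slower one that follows the burst slow wave, and a very slow
one that reflects the overall average.  The spike-band magnitude is
|c_fast - c_slow| and the slow-wave magnitude |c_slow - c_dc|; both are
smoothed by a running average.  The three readouts (averaged spike band,
averaged slow-wave band, DC level) are compared to calibrated setpoints to
produce the error signal that drives regulation.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "SensorConfig", "SensorFilters", "SensorTargets", "SensorErrors",
    "update_filters", "sensor_readouts", "sensor_errors", "calibrate_targets",
]


@dataclass(frozen=True)
class SensorConfig:
    """Filter time constants (ms).  The low-pass cascade must be ordered
    fast < slow < dc; the band-magnitude averaging window tau_avg only needs
    to be slower than the fast filter."""

    tau_fast: float = 50.0
    tau_slow: float = 1_000.0
    tau_dc: float = 60_000.0
    tau_avg: float = 5_000.0

    def __post_init__(self):
        if not (0 < self.tau_fast < self.tau_slow < self.tau_dc):
            raise ValueError(
                "sensor time constants must satisfy tau_fast < tau_slow < tau_dc")
        if self.tau_avg <= self.tau_fast:
            raise ValueError("tau_avg must exceed tau_fast")


@dataclass(frozen=True)
class SensorFilters:
    """Instantaneous filter state (all in μM)."""

    c_fast: float = 0.0
    c_slow: float = 0.0
    c_dc: float = 0.0
    a_fast: float = 0.0  # running average of |c_fast - c_slow|
    a_slow: float = 0.0  # running average of |c_slow - c_dc|

    def as_array(self) -> np.ndarray:
        return np.array([self.c_fast, self.c_slow, self.c_dc,
                         self.a_fast, self.a_slow])

    @staticmethod
    def from_array(a) -> "SensorFilters":
        return SensorFilters(*(float(x) for x in a))


@dataclass(frozen=True)
class SensorTargets:
    """Setpoints for the three readouts (μM)."""

    F_target: float
    S_target: float
    D_target: float

    def as_array(self) -> np.ndarray:
        return np.array([self.F_target, self.S_target, self.D_target])


@dataclass(frozen=True)
class SensorErrors:
    """Readout minus target, componentwise (μM)."""

    e_F: float
    e_S: float
    e_D: float

    def as_array(self) -> np.ndarray:
        return np.array([self.e_F, self.e_S, self.e_D])


def update_filters(filters: SensorFilters, Ca: float, dt: float,
                   config: SensorConfig = SensorConfig()) -> SensorFilters:
    """Advance the filter cascade one step of ``dt`` ms toward calcium ``Ca``."""
    if dt <= 0:
        raise ValueError("dt must be positive")
    kf = 1.0 - np.exp(-dt / config.tau_fast)
    ks = 1.0 - np.exp(-dt / config.tau_slow)
    kd = 1.0 - np.exp(-dt / config.tau_dc)
    ka = 1.0 - np.exp(-dt / config.tau_avg)
    c_fast = filters.c_fast + (Ca - filters.c_fast) * kf
    c_slow = filters.c_slow + (Ca - filters.c_slow) * ks
    c_dc = filters.c_dc + (Ca - filters.c_dc) * kd
    a_fast = filters.a_fast + (abs(c_fast - c_slow) - filters.a_fast) * ka
    a_slow = filters.a_slow + (abs(c_slow - c_dc) - filters.a_slow) * ka
    return SensorFilters(c_fast, c_slow, c_dc, a_fast, a_slow)


def sensor_readouts(filters: SensorFilters) -> tuple[float, float, float]:
    """(F̂, Ŝ, D̂): averaged spike-band and slow-wave magnitudes, DC level."""
    return filters.a_fast, filters.a_slow, filters.c_dc


def sensor_errors(readouts, targets: SensorTargets) -> SensorErrors:
    F, S, D = readouts
    return SensorErrors(F - targets.F_target, S - targets.S_target,
                        D - targets.D_target)


def equilibrated_filters(Ca: float,
                         targets: SensorTargets | None = None) -> SensorFilters:
    """Filter state with the low-passes settled at a constant ``Ca``.

    If targets are given, the averaged readouts start at their setpoints so
    that a calibrated model begins with zero sensor error.
    """
    f = SensorFilters(c_fast=Ca, c_slow=Ca, c_dc=Ca)
    if targets is not None:
        f = replace(f, a_fast=targets.F_target, a_slow=targets.S_target,
                    c_dc=targets.D_target)
    return f


def calibrate_targets(trace, window_s: float = 120.0) -> SensorTargets:
    """Setpoints = time-averaged readouts over the final ``window_s`` of a
    stable bursting trace.

    Raises if the window does not show bursting with at least 10 burst
    periods (measured by the burst detector on the recorded voltage).
    """
    from .burst import burst_statistics, classify_window, detect_spike_peaks

    t0 = trace.t_v[-1] - window_s
    mask = trace.t_v >= t0
    if classify_window(trace.V[mask], trace.t_v[mask]) != "bursting":
        raise ValueError("calibration requires a stable bursting reference")
    train = detect_spike_peaks(trace.V[mask], trace.t_v[mask])
    period, _, n_bursts = burst_statistics(train)
    if period is None or n_bursts < 10:
        raise ValueError(
            f"calibration window holds {n_bursts} bursts; need >= 10 periods")
    pmask = trace.t_p >= t0
    F, S, D = trace.readouts[pmask].mean(axis=0)
    return SensorTargets(float(F), float(S), float(D))
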