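"""High-extracellular-potassium perturbation schedules.

A schedule is an ordered list of contiguous epochs (baseline / perturbation /
wash).  Perturbation epochs shift the potassium reversal potential from
-80 mV to -55 mV and the leak reversal from -50 mV to -32 mV; baseline and
wash epochs use the baseline pair.  Epoch boundaries are half-open
[start, start + duration): the environment switches instantaneously.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

__all__ = [
    "BASELINE_E_K", "BASELINE_E_LEAK", "PERTURBED_E_K", "PERTURBED_E_LEAK",
    "Environment", "Epoch", "PerturbationSchedule",
    "build_schedule", "env_for_time",
]

BASELINE_E_K = -80.0
BASELINE_E_LEAK = -50.0
PERTURBED_E_K = -55.0
PERTURBED_E_LEAK = -32.0


@dataclass(frozen=True)
class Environment:
    """Extracellular condition seen by the neuron at one instant."""

    E_K: float  # mV
    E_leak: float  # mV
    epoch_label: str  # baseline | perturbation | wash


@dataclass(frozen=True)
class Epoch:
    label: str
    start: float  # s
    duration: float  # s
    E_K: float  # mV
    E_leak: float  # mV

    @property
    def end(self) -> float:
        return self.start + self.duration

    @property
    def environment(self) -> Environment:
        return Environment(E_K=self.E_K, E_leak=self.E_leak,
                           epoch_label=self.label)


@dataclass(frozen=True)
class PerturbationSchedule:
    epochs: tuple[Epoch, ...]

    @property
    def total_duration(self) -> float:
        return self.epochs[-1].end if self.epochs else 0.0

    @property
    def perturbation_epochs(self) -> tuple[Epoch, ...]:
        return tuple(e for e in self.epochs if e.label == "perturbation")

    @property
    def wash_epochs(self) -> tuple[Epoch, ...]:
        return tuple(e for e in self.epochs if e.label == "wash")

    def to_manifest(self) -> list[dict]:
        return [asdict(e) for e in self.epochs]


def build_schedule(lead_s: float = 600.0, n_cycles: int = 3,
                   pert_s: float = 1800.0, wash_s: float = 1800.0,
                   tail_s: float = 1800.0) -> PerturbationSchedule:
    """Baseline lead, then n cycles of (perturbation, wash); the final wash is
    extended by ``tail_s``.  Defaults give the 220-min three-cycle protocol."""
    for name, v in (("lead_s", lead_s), ("pert_s", pert_s),
                    ("wash_s", wash_s), ("tail_s", tail_s)):
        if v < 0:
            raise ValueError(f"{name} must be non-negative, got {v}")
    if n_cycles < 1:
        raise ValueError("n_cycles must be >= 1")

    epochs: list[Epoch] = []
    t = 0.0

    def add(label, duration, E_K, E_leak):
        nonlocal t
        if duration > 0:
            epochs.append(Epoch(label, t, duration, E_K, E_leak))
            t += duration

    add("baseline", lead_s, BASELINE_E_K, BASELINE_E_LEAK)
    for k in range(n_cycles):
        add("perturbation", pert_s, PERTURBED_E_K, PERTURBED_E_LEAK)
        wash = wash_s + (tail_s if k == n_cycles - 1 else 0.0)
        add("wash", wash, BASELINE_E_K, BASELINE_E_LEAK)
    return PerturbationSchedule(epochs=tuple(epochs))


def env_for_time(schedule: PerturbationSchedule, t: float) -> Environment:
    """Environment at time ``t`` (s); epochs are half-open [start, end)."""
    if not 0.0 <= t < schedule.total_duration:
        raise ValueError(
            f"t={t} outside schedule [0, {schedule.total_duration})")
    for epoch in schedule.epochs:
        if epoch.start <= t < epoch.end:
            return epoch.environment
    raise AssertionError("contiguous epochs must cover the schedule")
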