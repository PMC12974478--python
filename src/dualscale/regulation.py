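"""Dual-timescale activity-dependent regulation.

Two feedback processes act on the intrinsic parameter vector:

* maximal conductances follow the multiplicative law
  tau_g * dg_i/dt = -g_i * (W_g @ e)_i  (slow; tau_g = 600 s by default),
  which keeps every conductance strictly positive;
* half-(in)activation shifts follow the additive law
  tau_half * dDelta_j/dt = -(W_h @ e)_j - lambda * tau_half * Delta_j
  (fast; tau_half = 6 s), where the soft restoring rate ``lambda``
  discourages extreme shifts without imposing hard bounds.

Setting a time constant to infinity (or clearing the enable flag) freezes
that process.  The named variants map onto the ablation and timescale-
reversal experiments; swapping (tau_g, tau_half) is the complete "reversed"
configuration — no other code path changes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .channels import N_CHANNELS, N_CURVES
from .sensing import SensorErrors, SensorTargets

__all__ = [
    "RegulationConfig", "conductance_update", "halfshift_update",
    "make_regulation_config", "default_weights", "VARIANTS",
]

TAU_G_DEFAULT = 600.0  # s
TAU_HALF_DEFAULT = 6.0  # s
SOFT_PENALTY_DEFAULT = 1.0 / 60.0  # 1/s

#: cap on |d log g / dt| (1/s).  Channel insertion/removal rates are finite;
#: the cap is far above anything the standard slow process produces and only
#: engages when the conductance law is run at the fast timescale.
MAX_G_LOG_RATE = 0.005  # 1/s

#: per-channel (spike-band, slow-wave, DC) gain profile of the conductance
#: drive.  Positive entries down-regulate when the corresponding calcium
#: readout runs above target, so depolarizing currents carry positive rows
#: and hyperpolarizing currents negative rows.  The outward rows are
#: dominated by the DC term: a depolarization-block plateau (high average
#: calcium, no spike band) recruits potassium conductances strongly while
#: leaving the inward currents nearly untouched, which is what lets the
#: model find a high-potassium-tolerant configuration.
#: Channel order: Na, CaT, CaS, H, Kd, KCa, A.
G_WEIGHT_PROFILE = np.array([
    (0.02, 0.02, 0.1),     # Na
    (0.03, 0.03, 0.2),     # CaT
    (0.02, 0.02, 0.1),     # CaS
    (0.0, 0.0, 0.02),      # H
    (-0.03, -0.03, -0.15), # Kd
    (0.5, -0.75, -1.2),    # KCa
    (-0.02, -0.03, -0.15), # A
])

#: per-curve (spike-band, slow-wave, DC) gain profile of the half-shift
#: drive, chosen so a positive calcium error moves every curve in the
#: direction that lowers excitability (drive = -(W_h @ e): a negative row
#: shifts the curve toward depolarized voltages when the error is positive).
#: Curve order: activations (Na, CaT, CaS, H, Kd, KCa, A) then inactivations
#: (Na, CaT, CaS, A).  The A-activation row is deliberately weak: rapid
#: shifts of the transient potassium current would otherwise stand in for
#: the slow density change and erase the timescale separation the
#: architecture is built on.
H_WEIGHT_PROFILE = np.array([
    (-0.008, -0.015, -0.02),   # Na act
    (-0.008, -0.015, -0.02),   # CaT act
    (-0.008, -0.015, -0.02),   # CaS act
    (0.008, 0.015, 0.02),      # H act
    (0.008, 0.015, 0.02),      # Kd act
    (0.008, 0.015, 0.02),      # KCa act
    (0.0015, 0.003, 0.004),    # A act (weak)
    (0.008, 0.015, 0.02),      # Na inact
    (0.008, 0.015, 0.02),      # CaT inact
    (0.008, 0.015, 0.02),      # CaS inact
    (-0.008, -0.015, -0.02),   # A inact
])


@dataclass(frozen=True)
class RegulationConfig:
    tau_g: float = TAU_G_DEFAULT  # s; inf = frozen
    tau_half: float = TAU_HALF_DEFAULT  # s; inf = frozen
    conductance_weights: np.ndarray = field(
        default_factory=lambda: np.zeros((N_CHANNELS, 3)))
    halfshift_weights: np.ndarray = field(
        default_factory=lambda: np.zeros((N_CURVES, 3)))
    soft_penalty: float = SOFT_PENALTY_DEFAULT  # 1/s
    #: resting point of the soft restoring term; an ensemble member's own
    #: initial half-shift offsets, so the penalty discourages excursions
    #: without erasing the model's identity.  None means all-zero.
    shift_reference: np.ndarray | None = None
    enable_g: bool = True
    enable_half: bool = True
    variant: str = "custom"

    def __post_init__(self):
        if not (self.tau_g > 0):
            raise ValueError("tau_g must be positive (inf allowed)")
        if not (self.tau_half > 0):
            raise ValueError("tau_half must be positive (inf allowed)")

    @property
    def g_active(self) -> bool:
        return self.enable_g and math.isfinite(self.tau_g)

    @property
    def half_active(self) -> bool:
        return self.enable_half and math.isfinite(self.tau_half)


def default_weights(targets: SensorTargets):
    """(W_g, W_h) with physiological signs and gains normalized by the
    calibrated setpoints, so the drive responds to relative deviations."""
    t = targets.as_array()
    if np.any(t <= 0):
        raise ValueError("sensor targets must be strictly positive")
    W_g = G_WEIGHT_PROFILE / t
    W_h = H_WEIGHT_PROFILE / t
    return W_g, W_h


#: variant -> (tau_g, tau_half); infinities freeze the process entirely.
VARIANTS = {
    "full": (TAU_G_DEFAULT, TAU_HALF_DEFAULT),
    "half_only": (math.inf, TAU_HALF_DEFAULT),
    "gmax_only": (TAU_G_DEFAULT, math.inf),
    "reversed": (TAU_HALF_DEFAULT, TAU_G_DEFAULT),
    "half_disabled": (TAU_HALF_DEFAULT, math.inf),
}


def make_regulation_config(variant: str,
                           targets: SensorTargets | None = None,
                           soft_penalty: float = SOFT_PENALTY_DEFAULT,
                           shift_reference=None,
                           ) -> RegulationConfig:
    """Build the named regulation variant.

    ``full`` is the standard (600 s, 6 s) architecture; ``half_only`` and
    ``gmax_only`` freeze one process; ``reversed`` swaps the two time
    constants (6 s, 600 s); ``half_disabled`` is the reversed run with the
    half-shift process removed entirely (tau_g = 6 s, tau_half = inf).  When
    ``targets`` are given the default weight matrices are attached.
    """
    if variant not in VARIANTS:
        raise ValueError(
            f"unknown variant {variant!r}; choose from {sorted(VARIANTS)}")
    tau_g, tau_half = VARIANTS[variant]
    cfg = RegulationConfig(tau_g=tau_g, tau_half=tau_half,
                           soft_penalty=soft_penalty, variant=variant,
                           shift_reference=None if shift_reference is None
                           else np.asarray(shift_reference, dtype=float))
    if targets is not None:
        W_g, W_h = default_weights(targets)
        cfg = replace(cfg, conductance_weights=W_g, halfshift_weights=W_h)
    return cfg


def conductance_update(gmax, errors: SensorErrors, cfg: RegulationConfig,
                       dt: float):
    """One ``dt``-ms step of the multiplicative conductance law.

    The per-channel log-rate drive/tau_g is capped at ``MAX_G_LOG_RATE``,
    which keeps the multiplicative factor positive for any bounded error and
    bounds how fast channel densities can change.
    """
    gmax = np.asarray(gmax, dtype=float)
    if np.any(gmax <= 0):
        raise ValueError("maximal conductances must be strictly positive")
    if not cfg.g_active:
        return gmax.copy()
    rates = np.clip(cfg.conductance_weights @ errors.as_array() / cfg.tau_g,
                    -MAX_G_LOG_RATE, MAX_G_LOG_RATE)
    return gmax * (1.0 - (dt / 1000.0) * rates)


def halfshift_update(shifts, errors: SensorErrors, cfg: RegulationConfig,
                     dt: float):
    """One ``dt``-ms step of the half-shift law (no clipping of the shifts)."""
    shifts = np.asarray(shifts, dtype=float)
    if not cfg.half_active:
        return shifts.copy()
    drive = cfg.halfshift_weights @ errors.as_array()
    ref = (np.zeros_like(shifts) if cfg.shift_reference is None
           else cfg.shift_reference)
    dt_s = dt / 1000.0
    return shifts + dt_s * (-drive / cfg.tau_half
                            - cfg.soft_penalty * (shifts - ref))
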