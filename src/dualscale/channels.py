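"""Voltage-gated channel definitions for the seven-conductance bursting neuron.

The channel roster is the canonical single-compartment crustacean STG model:
fast sodium (Na), transient and slow calcium (CaT, CaS), hyperpolarization-
activated mixed cation (H), delayed-rectifier potassium (Kd), calcium-
activated potassium (KCa), and transient A-type potassium (A), plus an
unregulated ohmic leak.

Only the half-(in)activation voltages of the steady-state curves are
regulated (as additive shifts); slopes and gate time-constant functions are
fixed.  The 11 regulated curves are ordered: the 7 activation curves in
channel order, followed by the 4 inactivation curves (Na, CaT, CaS, A).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "CHANNEL_NAMES",
    "CHANNELS",
    "CURVE_LABELS",
    "N_CHANNELS",
    "N_CURVES",
    "ChannelDefinition",
    "gate_steady_state",
    "gate_tau",
    "build_gate_tables",
]

CHANNEL_NAMES = ("Na", "CaT", "CaS", "H", "Kd", "KCa", "A")
N_CHANNELS = 7
N_CURVES = 11

#: index of each channel in the 7-vector of regulated maximal conductances
CHANNEL_INDEX = {name: i for i, name in enumerate(CHANNEL_NAMES)}

#: channels whose current carries calcium into the cell
CALCIUM_CARRIERS = ("CaT", "CaS")


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


@dataclass(frozen=True)
class ChannelDefinition:
    """Static description of one voltage-gated channel population."""

    name: str
    activation_exponent: int
    has_inactivation: bool
    baseline_v_half_act: float  # mV
    slope_act: float  # mV, signed: negative = activated by hyperpolarization
    baseline_v_half_inact: float | None = None  # mV
    slope_inact: float | None = None  # mV
    reversal_mode: str = "fixed"  # "fixed" | "calcium-nernst"
    E_rev: float | None = None  # mV, fixed reversal (None for calcium-nernst / env K)
    env_reversal: str | None = None  # "K" if reversal follows the environment E_K
    calcium_coupling: bool = False  # KCa activation reads intracellular calcium

    @property
    def inactivation_exponent(self) -> int:
        return 1 if self.has_inactivation else 0


# Baseline half-voltages are the regulated quantities; everything else is a
# fixed kinetic constant of the model family.
CHANNELS: tuple[ChannelDefinition, ...] = (
    ChannelDefinition("Na", 3, True, -25.5, 5.29, -48.9, 5.18,
                      reversal_mode="fixed", E_rev=50.0),
    ChannelDefinition("CaT", 3, True, -27.1, 7.2, -32.1, 5.5,
                      reversal_mode="calcium-nernst"),
    ChannelDefinition("CaS", 3, True, -33.0, 8.1, -60.0, 6.2,
                      reversal_mode="calcium-nernst"),
    ChannelDefinition("H", 1, False, -70.0, -6.0,
                      reversal_mode="fixed", E_rev=-20.0),
    ChannelDefinition("Kd", 4, False, -12.3, 11.8,
                      reversal_mode="fixed", env_reversal="K"),
    ChannelDefinition("KCa", 4, False, -28.3, 12.6,
                      reversal_mode="fixed", env_reversal="K",
                      calcium_coupling=True),
    ChannelDefinition("A", 3, True, -27.2, 8.7, -56.9, 4.9,
                      reversal_mode="fixed", env_reversal="K"),
)

assert len(CHANNELS) == N_CHANNELS
assert sum(c.has_inactivation for c in CHANNELS) == 4

#: labels of the 11 regulated half-voltage curves, in shift-vector order
CURVE_LABELS = tuple(f"{c.name}_act" for c in CHANNELS) + tuple(
    f"{c.name}_inact" for c in CHANNELS if c.has_inactivation
)

#: per-curve (channel index, is_inactivation) in shift-vector order
CURVE_CHANNEL = tuple(
    [(i, False) for i in range(N_CHANNELS)]
    + [(i, True) for i, c in enumerate(CHANNELS) if c.has_inactivation]
)

#: baseline half-voltage per curve, shift-vector order (mV)
CURVE_BASELINES = np.array(
    [c.baseline_v_half_act for c in CHANNELS]
    + [c.baseline_v_half_inact for c in CHANNELS if c.has_inactivation]
)

#: signed slope per curve, shift-vector order (mV); inactivation stored negative
CURVE_SLOPES = np.array(
    [c.slope_act for c in CHANNELS]
    + [-c.slope_inact for c in CHANNELS if c.has_inactivation]
)


def gate_steady_state(V, v_half_base, shift, slope, kind="activation", Ca=None,
                      K_half_Ca=3.0):
    """Steady-state open fraction of one gating curve.

    Activation: 1/(1+exp(-(V - (v_half_base+shift))/slope)); inactivation uses
    the opposite sign.  ``slope`` must be positive; hyperpolarization-activated
    curves (H) are expressed by the internal channel table through a negative
    stored slope, not through this public contract.  For the KCa activation
    curve, pass the instantaneous intracellular calcium: the voltage sigmoid is
    scaled by Ca/(Ca + K_half_Ca).
    """
    if not np.all(np.isfinite(V)):
        raise ValueError("membrane voltage must be finite")
    if slope <= 0:
        raise ValueError("slope must be positive")
    x = (np.asarray(V, dtype=float) - (v_half_base + shift)) / slope
    if kind == "activation":
        out = _sigmoid(x)
    elif kind == "inactivation":
        out = _sigmoid(-x)
    else:
        raise ValueError(f"unknown gate kind {kind!r}")
    if Ca is not None:
        Ca = np.asarray(Ca, dtype=float)
        if np.any(Ca < 0):
            raise ValueError("calcium concentration must be non-negative")
        out = out * Ca / (Ca + K_half_Ca)
    return out


def curve_steady_state(curve_index, V, shift=0.0):
    """Steady-state value of regulated curve ``curve_index`` (internal form).

    Uses the signed-slope convention so H activation and all inactivation
    curves come out right; KCa calcium scaling is NOT applied here.
    """
    return _sigmoid((np.asarray(V, dtype=float) - (CURVE_BASELINES[curve_index] + shift))
                    / CURVE_SLOPES[curve_index])


# ---------------------------------------------------------------------------
# Fixed gate time-constant functions (ms).  These are unregulated kinetic
# constants of the model family; indexing follows CURVE_LABELS.
# ---------------------------------------------------------------------------

def _tau_na_m(V):
    return 1.32 - 1.26 / (1.0 + np.exp((V + 120.0) / -25.0))


# Slow component of inactivation-gate kinetics, active in a voltage window
# just below spike threshold.  Sustained depolarization (a high-potassium
# plateau) traps the h gates there, so neither the sodium spike nor the
# calcium slow wave can regenerate: the neuron sits in depolarization block.
# Ordinary inter-burst voltages (< -55 mV) and spike peaks are unaffected.
SLOW_WINDOW_V_MID = -45.0
SLOW_WINDOW_WIDTH = 7.0
NA_SLOW_TAU_MS = 500.0
CA_SLOW_TAU_MS = 2000.0


def _slow_window(V, amplitude):
    return amplitude * np.exp(-(((V - SLOW_WINDOW_V_MID) / SLOW_WINDOW_WIDTH) ** 2))


def _tau_na_h(V):
    fast = (0.67 / (1.0 + np.exp((V + 62.9) / -10.0))) * (
        1.5 + 1.0 / (1.0 + np.exp((V + 34.9) / 3.6))
    )
    return fast + _slow_window(V, NA_SLOW_TAU_MS)


def _tau_cat_m(V):
    return 21.7 - 21.3 / (1.0 + np.exp((V + 68.1) / -20.5))


def _tau_cat_h(V):
    fast = 105.0 - 89.8 / (1.0 + np.exp((V + 55.0) / -16.9))
    return fast + _slow_window(V, CA_SLOW_TAU_MS)


def _tau_cas_m(V):
    return 1.4 + 7.0 / (np.exp((V + 27.0) / 10.0) + np.exp((V + 70.0) / -13.0))


def _tau_cas_h(V):
    fast = 60.0 + 150.0 / (np.exp((V + 55.0) / 9.0) + np.exp((V + 65.0) / -16.0))
    return fast + _slow_window(V, CA_SLOW_TAU_MS)


def _tau_h_m(V):
    return 272.0 + 1499.0 / (1.0 + np.exp((V + 42.2) / -8.73))


def _tau_kd_m(V):
    return 7.2 - 6.4 / (1.0 + np.exp((V + 28.3) / -19.2))


def _tau_kca_m(V):
    return 90.3 - 75.1 / (1.0 + np.exp((V + 46.0) / -22.7))


def _tau_a_m(V):
    return 11.6 - 10.4 / (1.0 + np.exp((V + 32.9) / -15.2))


def _tau_a_h(V):
    return 38.6 - 29.2 / (1.0 + np.exp((V + 38.9) / -26.5))


_TAU_FUNCS = (
    _tau_na_m, _tau_cat_m, _tau_cas_m, _tau_h_m, _tau_kd_m, _tau_kca_m,
    _tau_a_m,
    _tau_na_h, _tau_cat_h, _tau_cas_h, _tau_a_h,
)


def gate_tau(curve_index, V):
    """Fixed time constant (ms) of the gate belonging to curve ``curve_index``."""
    return _TAU_FUNCS[curve_index](np.asarray(V, dtype=float))


@dataclass(frozen=True)
class GateTables:
    """Lookup tables over a voltage grid for the compiled inner loop."""

    v_min: float
    dv: float
    inf: np.ndarray  # (11, NV) steady-state curves at baseline half-voltage
    relax: np.ndarray  # (11, NV) 1 - exp(-dt/tau(V)); depends on dt
    dt: float
    n: int = field(init=False)

    def __post_init__(self):
        object.__setattr__(self, "n", self.inf.shape[1])


def build_gate_tables(dt, v_min=-200.0, v_max=100.0, dv=0.05) -> GateTables:
    """Precompute per-gate steady-state and relaxation tables.

    Half-voltage shifts are applied at lookup time by evaluating the baseline
    steady-state table at V - shift, so one table serves all models.
    """
    grid = np.arange(v_min, v_max + dv / 2, dv)
    inf = np.empty((N_CURVES, grid.size))
    relax = np.empty((N_CURVES, grid.size))
    for j in range(N_CURVES):
        inf[j] = _sigmoid((grid - CURVE_BASELINES[j]) / CURVE_SLOPES[j])
        relax[j] = 1.0 - np.exp(-dt / _TAU_FUNCS[j](grid))
    return GateTables(v_min=float(v_min), dv=float(dv), inf=inf, relax=relax,
                      dt=float(dt))
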