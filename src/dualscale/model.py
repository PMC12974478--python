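"""Single-compartment bursting neuron with regulated intrinsic parameters.

Units: voltage mV, time ms inside the integrator (seconds at the schedule
level), conductance μS, current nA, capacitance nF, calcium μM.  Outward
current is positive, so C dV/dt = -ΣI.

Two integration paths exist: :func:`step_dynamics` is the plain-Python
reference step used by the unit tests, and :func:`simulate` drives the
numba-compiled kernel over a full perturbation schedule.  Both implement the
same update order (gates by exponential Euler at the pre-step voltage, then
currents, then forward-Euler voltage/calcium, then sensors, then
regulation); the kernel looks gating curves up in tables while the reference
step evaluates them directly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from . import channels as ch
from ._kernel import STATUS_OK, run_kernel
from .protocol import Environment, PerturbationSchedule
from .regulation import (MAX_G_LOG_RATE, RegulationConfig,
                         conductance_update, halfshift_update)
from .sensing import (SensorConfig, SensorErrors, SensorFilters,
                      SensorTargets, equilibrated_filters, sensor_errors,
                      sensor_readouts, update_filters)

__all__ = [
    "ModelConstants", "IntrinsicState", "DynamicState", "SimulationTrace",
    "IntegrationError", "nernst_reversal", "ionic_current",
    "initial_dynamic_state", "step_dynamics", "simulate",
]

GAS_CONSTANT = 8.314462618  # J/(mol K)
FARADAY = 96485.33212  # C/mol

MAX_STABLE_DT = 0.1  # ms


class IntegrationError(RuntimeError):
    """Raised when a state element becomes non-finite during integration."""

    def __init__(self, element: str, time_s: float):
        self.element = element
        self.time_s = time_s
        super().__init__(
            f"integration failure: non-finite {element} at t = {time_s:.3f} s")


@dataclass(frozen=True)
class ModelConstants:
    """Calibration constants of the model family (not regulated)."""

    C: float = 0.628  # nF
    tau_ca: float = 200.0  # ms
    f_ca: float = 14.96  # μM/nA
    ca_rest: float = 0.05  # μM
    ca_out: float = 3.0  # mM extracellular calcium
    temperature: float = 283.0  # K
    kca_half: float = 3.0  # μM, KCa half-saturation
    E_Na: float = 50.0  # mV
    E_H: float = -20.0  # mV

    @property
    def e_ca_coef(self) -> float:
        # RT/(2F) in mV, for the per-step calcium Nernst potential
        return 1e3 * GAS_CONSTANT * self.temperature / (2.0 * FARADAY)


DEFAULT_CONSTANTS = ModelConstants()


@dataclass(frozen=True)
class IntrinsicState:
    """The regulated parameter vector: 7 conductances + 11 half-shifts."""

    gmax: np.ndarray  # μS, channel order Na..A, strictly positive
    half_shifts: np.ndarray  # mV, curve order (7 act + 4 inact)
    leak_g: float = 0.00628  # μS, fixed and unregulated

    def __post_init__(self):
        g = np.asarray(self.gmax, dtype=float)
        s = np.asarray(self.half_shifts, dtype=float)
        if g.shape != (ch.N_CHANNELS,):
            raise ValueError(f"gmax must have shape (7,), got {g.shape}")
        if s.shape != (ch.N_CURVES,):
            raise ValueError(f"half_shifts must have shape (11,), got {s.shape}")
        if np.any(g <= 0):
            raise ValueError("maximal conductances must be strictly positive")
        object.__setattr__(self, "gmax", g)
        object.__setattr__(self, "half_shifts", s)


@dataclass(frozen=True)
class DynamicState:
    """Instantaneous membrane / gating / calcium / sensor state."""

    V: float  # mV
    gates: np.ndarray  # 11 values in [0, 1], gate order = curve order
    Ca: float  # μM
    filters: SensorFilters
    t: float = 0.0  # s


@dataclass
class SimulationTrace:
    """Recorded time series of one run."""

    t_v: np.ndarray  # s
    V: np.ndarray  # mV
    Ca: np.ndarray  # μM
    t_p: np.ndarray  # s
    gmax: np.ndarray  # (n_p, 7) μS
    half_shifts: np.ndarray  # (n_p, 11) mV
    readouts: np.ndarray  # (n_p, 3) μM
    errors: np.ndarray  # (n_p, 3) μM
    dt: float  # ms
    record_interval: float  # ms, voltage/calcium sampling
    param_interval: float  # ms, parameter sampling
    schedule: PerturbationSchedule
    final_state: DynamicState
    intrinsic_initial: IntrinsicState
    intrinsic_final: IntrinsicState


def nernst_reversal(conc_in: float, conc_out: float, valence: int,
                    temperature: float) -> float:
    """Nernst potential (mV) for concentrations in matching units."""
    if conc_in <= 0 or conc_out <= 0:
        raise ValueError("concentrations must be strictly positive")
    return (1e3 * GAS_CONSTANT * temperature / (valence * FARADAY)
            * math.log(conc_out / conc_in))


def ionic_current(gmax: float, m: float, h: float, p: int, q: int,
                  V: float, E_rev: float) -> float:
    """gmax · m^p · h^q · (V - E_rev), outward positive (nA)."""
    if gmax < 0:
        raise ValueError("gmax must be non-negative")
    return gmax * m ** p * h ** q * (V - E_rev)


def _gate_steady_states(V: float, shifts, Ca: float,
                        constants: ModelConstants) -> np.ndarray:
    inf = np.empty(ch.N_CURVES)
    for j in range(ch.N_CURVES):
        inf[j] = ch.curve_steady_state(j, V, shifts[j])
    inf[5] *= Ca / (Ca + constants.kca_half)  # KCa activation reads calcium
    return inf


def initial_dynamic_state(intrinsic: IntrinsicState,
                          V: float = -55.0, Ca: float = 0.2,
                          targets: SensorTargets | None = None,
                          constants: ModelConstants = DEFAULT_CONSTANTS,
                          ) -> DynamicState:
    """Gates at steady state for ``V``; sensor filters equilibrated."""
    gates = _gate_steady_states(V, intrinsic.half_shifts, Ca, constants)
    return DynamicState(V=V, gates=gates, Ca=Ca,
                        filters=equilibrated_filters(Ca, targets), t=0.0)


def membrane_currents(state: DynamicState, intrinsic: IntrinsicState,
                      env: Environment,
                      constants: ModelConstants = DEFAULT_CONSTANTS):
    """(total conductance μS, conductance-weighted reversal sum μS·mV,
    calcium-carried current nA)."""
    V, Ca = state.V, max(state.Ca, 1e-9)
    E_Ca = constants.e_ca_coef * math.log(constants.ca_out * 1e3 / Ca)
    g_tot = intrinsic.leak_g
    gE_tot = intrinsic.leak_g * env.E_leak
    i_ca = 0.0
    for i, cdef in enumerate(ch.CHANNELS):
        m = state.gates[i]
        h = state.gates[ch.CURVE_LABELS.index(f"{cdef.name}_inact")] \
            if cdef.has_inactivation else 1.0
        if cdef.reversal_mode == "calcium-nernst":
            E = E_Ca
        elif cdef.env_reversal == "K":
            E = env.E_K
        else:
            E = cdef.E_rev
        ge = intrinsic.gmax[i] * m ** cdef.activation_exponent \
            * h ** cdef.inactivation_exponent
        g_tot += ge
        gE_tot += ge * E
        if cdef.name in ch.CALCIUM_CARRIERS:
            i_ca += ge * (V - E)
    return g_tot, gE_tot, i_ca


def step_dynamics(state: DynamicState, intrinsic: IntrinsicState,
                  env: Environment, dt: float,
                  regulation: RegulationConfig | None = None,
                  targets: SensorTargets | None = None,
                  constants: ModelConstants = DEFAULT_CONSTANTS,
                  sensor_config: SensorConfig = SensorConfig(),
                  ) -> tuple[DynamicState, IntrinsicState]:
    """Advance the full state by one step of ``dt`` ms (reference path).

    Returns the new dynamic and intrinsic states; the intrinsic state is
    unchanged when ``regulation`` is None or fully frozen.
    """
    if not (0 < dt <= MAX_STABLE_DT):
        raise ValueError(f"dt must be in (0, {MAX_STABLE_DT}] ms")
    V, Ca = state.V, max(state.Ca, 1e-9)

    # gates: exponential Euler toward steady state at the pre-step voltage
    inf = _gate_steady_states(V, intrinsic.half_shifts, Ca, constants)
    relax = 1.0 - np.exp(-dt / np.array(
        [ch.gate_tau(j, V) for j in range(ch.N_CURVES)]))
    gates = state.gates + (inf - state.gates) * relax

    mid = DynamicState(V=V, gates=gates, Ca=Ca, filters=state.filters,
                       t=state.t)
    g_tot, gE_tot, i_ca = membrane_currents(mid, intrinsic, env, constants)

    # exponential Euler toward the instantaneous membrane equilibrium
    V_new = V + (gE_tot / g_tot - V) * (1.0 - math.exp(-dt * g_tot / constants.C))
    Ca_new = Ca + dt * (-constants.f_ca * i_ca - Ca
                        + constants.ca_rest) / constants.tau_ca

    filters = update_filters(state.filters, Ca_new, dt, sensor_config)

    new_intrinsic = intrinsic
    if regulation is not None and targets is not None:
        errs = sensor_errors(sensor_readouts(filters), targets)
        gmax = conductance_update(intrinsic.gmax, errs, regulation, dt)
        shifts = halfshift_update(intrinsic.half_shifts, errs, regulation, dt)
        new_intrinsic = replace(intrinsic, gmax=gmax, half_shifts=shifts)

    t_new = state.t + dt * 1e-3
    if not (np.isfinite(V_new) and np.isfinite(Ca_new)
            and np.all(np.isfinite(gates))):
        element = "V" if not np.isfinite(V_new) else (
            "Ca" if not np.isfinite(Ca_new) else "gates")
        raise IntegrationError(element, t_new)
    return (DynamicState(V=V_new, gates=gates, Ca=max(Ca_new, 0.0),
                         filters=filters, t=t_new), new_intrinsic)


_TABLE_CACHE: dict[float, ch.GateTables] = {}


def _tables_for(dt: float) -> ch.GateTables:
    tab = _TABLE_CACHE.get(dt)
    if tab is None:
        tab = ch.build_gate_tables(dt)
        _TABLE_CACHE[dt] = tab
    return tab


def simulate(intrinsic: IntrinsicState, schedule: PerturbationSchedule,
             regulation: RegulationConfig | None = None,
             dt: float = 0.05, record_interval: float = 1.0,
             param_interval: float = 1000.0,
             targets: SensorTargets | None = None,
             initial: DynamicState | None = None,
             constants: ModelConstants = DEFAULT_CONSTANTS,
             sensor_config: SensorConfig = SensorConfig(),
             ) -> SimulationTrace:
    """Run the compiled integrator over a full schedule.

    ``record_interval`` (ms) sets the voltage/calcium sampling and
    ``param_interval`` (ms) the intrinsic-parameter/sensor sampling.  The run
    is deterministic: identical inputs produce identical traces.  When
    ``regulation`` is None (or both processes frozen) the intrinsic
    parameters stay constant for the whole run.
    """
    if not schedule.epochs:
        raise ValueError("schedule must contain at least one epoch")
    if not (0 < dt <= MAX_STABLE_DT):
        raise ValueError(f"dt must be in (0, {MAX_STABLE_DT}] ms")
    if record_interval < dt:
        raise ValueError("record_interval must be >= dt")

    if regulation is None:
        regulation = RegulationConfig(tau_g=math.inf, tau_half=math.inf,
                                      enable_g=False, enable_half=False,
                                      variant="frozen")
    if (regulation.g_active or regulation.half_active) and targets is None:
        raise ValueError("active regulation requires sensor targets")
    tgt = targets if targets is not None else SensorTargets(0.0, 0.0, 0.0)

    if initial is None:
        initial = initial_dynamic_state(intrinsic, targets=targets,
                                        constants=constants)

    n_steps = int(round(schedule.total_duration * 1e3 / dt))
    rec_v = max(1, int(round(record_interval / dt)))
    rec_p = max(1, int(round(param_interval / dt)))
    n_v = (n_steps + rec_v - 1) // rec_v
    n_p = (n_steps + rec_p - 1) // rec_p

    epoch_end_step = np.array(
        [int(round(e.end * 1e3 / dt)) for e in schedule.epochs], dtype=np.int64)
    epoch_EK = np.array([e.E_K for e in schedule.epochs])
    epoch_Eleak = np.array([e.E_leak for e in schedule.epochs])

    tab = _tables_for(dt)
    g = np.asarray(intrinsic.gmax, dtype=float).copy()
    shifts = np.asarray(intrinsic.half_shifts, dtype=float).copy()

    V_out = np.empty(n_v)
    Ca_out = np.empty(n_v)
    g_out = np.empty((n_p, ch.N_CHANNELS))
    sh_out = np.empty((n_p, ch.N_CURVES))
    ro_out = np.empty((n_p, 3))
    er_out = np.empty((n_p, 3))
    state_out = np.empty(18)

    k_fast = 1.0 - math.exp(-dt / sensor_config.tau_fast)
    k_slow = 1.0 - math.exp(-dt / sensor_config.tau_slow)
    k_dc = 1.0 - math.exp(-dt / sensor_config.tau_dc)
    k_avg = 1.0 - math.exp(-dt / sensor_config.tau_avg)

    inv_tau_g = 1.0 / regulation.tau_g if regulation.g_active else 0.0
    inv_tau_half = (1.0 / regulation.tau_half
                    if regulation.half_active else 0.0)

    status, fail_step = run_kernel(
        dt, n_steps, epoch_end_step, epoch_EK, epoch_Eleak,
        g, float(intrinsic.leak_g), shifts,
        tab.inf, tab.relax, tab.v_min, tab.dv,
        constants.C, constants.tau_ca, constants.f_ca, constants.ca_rest,
        constants.e_ca_coef, constants.ca_out * 1e3, constants.kca_half,
        constants.E_Na, constants.E_H,
        k_fast, k_slow, k_dc, k_avg, tgt.as_array(),
        np.ascontiguousarray(regulation.conductance_weights, dtype=float),
        np.ascontiguousarray(regulation.halfshift_weights, dtype=float),
        inv_tau_g, inv_tau_half, regulation.soft_penalty,
        MAX_G_LOG_RATE,
        (np.zeros(ch.N_CURVES) if regulation.shift_reference is None
         else np.asarray(regulation.shift_reference, dtype=float)),
        float(initial.V), np.asarray(initial.gates, dtype=float),
        float(initial.Ca), initial.filters.as_array(),
        rec_v, rec_p,
        V_out, Ca_out, g_out, sh_out, ro_out, er_out, state_out,
    )
    if status != STATUS_OK:
        raise IntegrationError("V", fail_step * dt * 1e-3)
    # fastmath elides NaN checks inside the kernel; verify the recorded trace
    bad = ~np.isfinite(V_out)
    if bad.any():
        raise IntegrationError("V", float(np.flatnonzero(bad)[0]
                                          * rec_v * dt * 1e-3))
    bad = ~np.isfinite(Ca_out)
    if bad.any():
        raise IntegrationError("Ca", float(np.flatnonzero(bad)[0]
                                           * rec_v * dt * 1e-3))

    final = DynamicState(
        V=float(state_out[0]), gates=state_out[1:12].copy(),
        Ca=float(state_out[12]),
        filters=SensorFilters.from_array(state_out[13:18]),
        t=initial.t + n_steps * dt * 1e-3)
    intrinsic_final = replace(intrinsic, gmax=g, half_shifts=shifts)
    return SimulationTrace(
        t_v=np.arange(n_v) * (rec_v * dt * 1e-3),
        V=V_out, Ca=Ca_out,
        t_p=np.arange(n_p) * (rec_p * dt * 1e-3),
        gmax=g_out, half_shifts=sh_out, readouts=ro_out, errors=er_out,
        dt=dt, record_interval=rec_v * dt, param_interval=rec_p * dt,
        schedule=schedule, final_state=final,
        intrinsic_initial=intrinsic, intrinsic_final=intrinsic_final)
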