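"""Numba-compiled inner integration loop.

Layout conventions (shared with :mod:`dualscale.channels`):

* channels: Na, CaT, CaS, H, Kd, KCa, A  (7 regulated conductances)
* gates/curves: the 7 activation gates in channel order, then the 4
  inactivation gates (Na, CaT, CaS, A); gate j is governed by regulated
  curve j, so the 11-vector of half-shifts aligns one-to-one with gates.

Steady-state curves are looked up in a table at V - shift (shifting a
midpoint is a translation of the curve); relaxation factors
1 - exp(-dt/tau(V)) are looked up at V.  Gates use exponential Euler,
voltage and calcium forward Euler, regulation forward Euler with the
multiplicative conductance factor clamped to stay positive.
"""

import numpy as np
from numba import njit

STATUS_OK = 0
STATUS_NONFINITE = 1

# activation exponents per channel
_P = np.array([3, 3, 3, 1, 4, 4, 3], dtype=np.int64)
# inactivation gate index per channel (-1 = none)
_HIDX = np.array([7, 8, 9, -1, -1, -1, 10], dtype=np.int64)


@njit(cache=True, fastmath=True)
def _interp(tab, j, x):
    n = tab.shape[1]
    if x <= 0.0:
        return tab[j, 0]
    if x >= n - 1:
        return tab[j, n - 1]
    i = int(x)
    fr = x - i
    return tab[j, i] * (1.0 - fr) + tab[j, i + 1] * fr


@njit(cache=True, fastmath=True)
def run_kernel(
    dt,                     # ms
    n_steps,
    epoch_end_step,         # int64[n_epochs], cumulative step counts
    epoch_EK, epoch_Eleak,  # float64[n_epochs]
    g, leak_g, shifts,      # float64[7], float, float64[11]; mutated in place
    inf_tab, relax_tab,     # (11, NV)
    v_min, dv,
    # constants
    C, tau_ca, f_ca, ca_rest, e_ca_coef, ca_out_um, kca_half, E_Na, E_H,
    # sensor relaxation factors per step and targets
    k_fast, k_slow, k_dc, k_avg, targets,  # float64[3]
    # regulation
    Wg, Wh, inv_tau_g, inv_tau_half, lam, max_g_rate, shift_ref,
    # initial dynamic state
    V0, gates0, Ca0, filt0,  # gates0 float64[11], filt0 float64[5]
    # recording (preallocated)
    rec_v_every, rec_p_every,
    V_out, Ca_out, g_out, sh_out, ro_out, er_out,
    state_out,  # float64[18]: V, 11 gates, Ca, 5 filter states
):
    V = V0
    Ca = Ca0
    gates = gates0.copy()
    c_fast, c_slow, c_dc, a_fast, a_slow = (
        filt0[0], filt0[1], filt0[2], filt0[3], filt0[4])
    dt_s = dt * 1e-3

    ep = 0
    n_ep = epoch_end_step.shape[0]
    EK = epoch_EK[0]
    Eleak = epoch_Eleak[0]

    iv = 0
    ip = 0
    for step in range(n_steps):
        while ep < n_ep - 1 and step >= epoch_end_step[ep]:
            ep += 1
            EK = epoch_EK[ep]
            Eleak = epoch_Eleak[ep]

        # record before stepping so sample k sits at t = k * rec * dt
        if step % rec_v_every == 0 and iv < V_out.shape[0]:
            if not (np.isfinite(V) and np.isfinite(Ca)):
                return STATUS_NONFINITE, step
            V_out[iv] = V
            Ca_out[iv] = Ca
            iv += 1
        if step % rec_p_every == 0 and ip < g_out.shape[0]:
            for i in range(7):
                g_out[ip, i] = g[i]
            for j in range(11):
                sh_out[ip, j] = shifts[j]
            ro_out[ip, 0] = a_fast
            ro_out[ip, 1] = a_slow
            ro_out[ip, 2] = c_dc
            er_out[ip, 0] = a_fast - targets[0]
            er_out[ip, 1] = a_slow - targets[1]
            er_out[ip, 2] = c_dc - targets[2]
            ip += 1

        # reversal potentials
        if Ca < 1e-9:
            Ca = 1e-9
        E_Ca = e_ca_coef * np.log(ca_out_um / Ca)

        # gate relaxation (exponential Euler via table lookup)
        x_tau = (V - v_min) / dv
        for j in range(11):
            x_inf = (V - shifts[j] - v_min) / dv
            m_inf = _interp(inf_tab, j, x_inf)
            if j == 5:  # KCa activation scales with calcium
                m_inf *= Ca / (Ca + kca_half)
            k = _interp(relax_tab, j, x_tau)
            gates[j] += (m_inf - gates[j]) * k

        # effective conductances (outward positive currents)
        g_tot = leak_g
        gE_tot = leak_g * Eleak
        I_ca_total = 0.0
        for i in range(7):
            m = gates[i]
            if _P[i] == 3:
                act = m * m * m
            elif _P[i] == 4:
                m2 = m * m
                act = m2 * m2
            else:
                act = m
            h = 1.0
            hi = _HIDX[i]
            if hi >= 0:
                h = gates[hi]
            if i == 0:
                E = E_Na
            elif i == 1 or i == 2:
                E = E_Ca
            elif i == 3:
                E = E_H
            else:
                E = EK
            ge = g[i] * act * h
            g_tot += ge
            gE_tot += ge * E
            if i == 1 or i == 2:
                I_ca_total += ge * (V - E)

        # membrane by exponential Euler toward the instantaneous equilibrium;
        # calcium by forward Euler (linear, non-stiff at this dt)
        V += (gE_tot / g_tot - V) * (1.0 - np.exp(-dt * g_tot / C))
        Ca += dt * (-f_ca * I_ca_total - Ca + ca_rest) / tau_ca

        # sensor cascade
        c_fast += (Ca - c_fast) * k_fast
        c_slow += (Ca - c_slow) * k_slow
        c_dc += (Ca - c_dc) * k_dc
        a_fast += (abs(c_fast - c_slow) - a_fast) * k_avg
        a_slow += (abs(c_slow - c_dc) - a_slow) * k_avg

        e0 = a_fast - targets[0]
        e1 = a_slow - targets[1]
        e2 = c_dc - targets[2]

        # regulation
        if inv_tau_g > 0.0:
            for i in range(7):
                drive = Wg[i, 0] * e0 + Wg[i, 1] * e1 + Wg[i, 2] * e2
                rate = drive * inv_tau_g
                if rate > max_g_rate:
                    rate = max_g_rate
                elif rate < -max_g_rate:
                    rate = -max_g_rate
                g[i] *= 1.0 - dt_s * rate
        if inv_tau_half > 0.0:
            for j in range(11):
                drive = Wh[j, 0] * e0 + Wh[j, 1] * e1 + Wh[j, 2] * e2
                shifts[j] += dt_s * (-drive * inv_tau_half
                                     - lam * (shifts[j] - shift_ref[j]))

    state_out[0] = V
    for j in range(11):
        state_out[1 + j] = gates[j]
    state_out[12] = Ca
    state_out[13] = c_fast
    state_out[14] = c_slow
    state_out[15] = c_dc
    state_out[16] = a_fast
    state_out[17] = a_slow
    if not (np.isfinite(V) and np.isfinite(Ca)):
        return STATUS_NONFINITE, n_steps
    return STATUS_OK, n_steps
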