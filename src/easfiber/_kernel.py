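"""Numba forward-Euler kernel for the two-point-neuron electric model.

The kernel integrates the peripheral and central adaptive exponential
integrate-and-fire neurons on a shared time grid.  It is shared by the
ES-alone, coupled and alternative model variants:

* ES-alone: electric drive only;
* coupled: a per-trial synaptic current (suprathreshold rectangular
  injections, one per neurotransmitter release) is added to the
  peripheral drive;
* alternative ("spike exchange"): release events feed a classic
  spike-generator with refractory period ``t_abs + Exp(t_rel)``; spikes
  from either the membrane or the generator reset both systems.

Internal unit system: time s, potential mV, current µA, conductance mS,
capacitance nF.  With these units ``dV/dt [mV/s] = 1e6 * I[µA] / C[nF]``.

Parameter-vector layout (float64, length 19)::

    0 dt        5 tau_sub   10 C_cen    15 tau_supra_per
    1 E_L       6 a_sub     11 g_L_per  16 tau_supra_cen
    2 V_T       7 a_supra   12 g_L_cen  17 dead_steps
    3 V_peak    8 b         13 DT_per   18 abs_steps (alt mode)
    4 V_reset   9 C_per     14 DT_cen
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

#: Clamp for the exponential-term argument; beyond this the membrane is
#: guaranteed to reach V_peak within one step anyway.
_EXP_CLAMP = 25.0

# State-vector layout: V_per, V_cen, Isub_per, Isub_cen, Isup_per, Isup_cen
N_STATE = 6


@njit(cache=True, fastmath=True)
def _integrate_trial(p, elec_per, elec_cen, syn_per, noise_per, noise_cen,
                     rel_idx, rrp_draw_steps, state, out_t, out_w):
    """Integrate one trial; returns the number of spikes emitted.

    Spike times are written to ``out_t`` (seconds from trace start) and
    the spike source to ``out_w`` (0 peripheral, 1 central, 2 acoustic
    spike generator, alternative mode only).  ``state`` is updated in
    place to the final membrane state.
    """
    dt = p[0]
    E_L = p[1]; V_T = p[2]; V_peak = p[3]; V_reset = p[4]
    tau_sub = p[5]; a_sub = p[6]; a_supra = p[7]; b = p[8]
    Cp = p[9]; Cc = p[10]; gLp = p[11]; gLc = p[12]
    DTp = p[13]; DTc = p[14]; tsp = p[15]; tsc = p[16]
    dead_steps = int(p[17])
    abs_steps = int(p[18])

    kp = dt * 1e6 / Cp
    kc = dt * 1e6 / Cc
    r_sub = dt / tau_sub
    r_sup_p = dt / tsp
    r_sup_c = dt / tsc

    Vp = state[0]; Vc = state[1]
    Jsub_p = state[2]; Jsub_c = state[3]
    Jsup_p = state[4]; Jsup_c = state[5]

    n = elec_per.shape[0]
    use_syn = syn_per.shape[0] == n
    n_rel = rel_idx.shape[0]
    i_rel = 0
    n_draw = rrp_draw_steps.shape[0]
    i_draw = 0

    refr_end = -1       # first sample index at which the membrane may spike
    as_refr_end = -1    # alternative-mode spike-generator refractory end
    n_sp = 0

    for j in range(n):
        # Alternative coupling: releases hitting a non-refractory spike
        # generator become spikes and reset both systems.
        while i_rel < n_rel and rel_idx[i_rel] == j:
            i_rel += 1
            if j >= as_refr_end:
                out_t[n_sp] = j * dt
                out_w[n_sp] = 2
                n_sp += 1
                Vp = V_reset; Vc = V_reset
                Jsup_p += b; Jsup_c += b
                refr_end = j + dead_steps
                as_refr_end = j + abs_steps + int(rrp_draw_steps[i_draw % n_draw])
                i_draw += 1

        # External drive (electric and synaptic) is gated off during the
        # absolute refractory period; noise and adaptation continue.
        if j < refr_end:
            dp = 0.0
            dc = 0.0
        else:
            dp = elec_per[j]
            dc = elec_cen[j]
            if use_syn:
                dp += syn_per[j]

        ap = (Vp - V_T) / DTp
        if ap > _EXP_CLAMP:
            ap = _EXP_CLAMP
        hp = -gLp * (Vp - E_L) + gLp * DTp * math.exp(ap)
        ac = (Vc - V_T) / DTc
        if ac > _EXP_CLAMP:
            ac = _EXP_CLAMP
        hc = -gLc * (Vc - E_L) + gLc * DTc * math.exp(ac)

        Ip = hp - Jsub_p - Jsup_p + noise_per[j] + dp
        Ic = hc - Jsub_c - Jsup_c + noise_cen[j] + dc

        Vp_new = Vp + kp * Ip
        Vc_new = Vc + kc * Ic
        Jsub_p += r_sub * (a_sub * (Vp - E_L) - Jsub_p)
        Jsub_c += r_sub * (a_sub * (Vc - E_L) - Jsub_c)
        Jsup_p += r_sup_p * (a_supra * (Vp - E_L) - Jsup_p)
        Jsup_c += r_sup_c * (a_supra * (Vc - E_L) - Jsup_c)
        Vp = Vp_new
        Vc = Vc_new

        if Vp >= V_peak or Vc >= V_peak:
            # clamp the exponential runaway at the detection potential
            which = 0 if Vp >= V_peak else 1
            if Vp > V_peak:
                Vp = V_peak
            if Vc > V_peak:
                Vc = V_peak
            if j + 1 >= refr_end:
                out_t[n_sp] = (j + 1) * dt
                out_w[n_sp] = which
                n_sp += 1
                Vp = V_reset; Vc = V_reset
                Jsup_p += b; Jsup_c += b
                refr_end = j + 1 + dead_steps
                if n_rel > 0:
                    as_refr_end = j + 1 + abs_steps + int(
                        rrp_draw_steps[i_draw % n_draw])
                    i_draw += 1

    state[0] = Vp; state[1] = Vc
    state[2] = Jsub_p; state[3] = Jsub_c
    state[4] = Jsup_p; state[5] = Jsup_c
    return n_sp


@njit(cache=True)
def integrate_batch(p, elec_per, elec_cen, syn_per, noise_per, noise_cen,
                    rel_idx_flat, rel_offsets, rrp_draw_steps,
                    states, out_t, out_w, out_n):
    """Integrate a batch of trials sharing the electric drive.

    Parameters
    ----------
    p : parameter vector (see module docstring)
    elec_per, elec_cen : (n_steps,) electric drive per neuron (µA)
    syn_per : (n_trials, n_steps) synaptic peripheral drive (µA) or a
        (0, 0) array when unused
    noise_per, noise_cen : (n_trials, n_steps) noise currents (µA)
    rel_idx_flat, rel_offsets : flattened per-trial release sample
        indices (alternative mode; empty otherwise)
    rrp_draw_steps : (n_trials, n_draw) pre-drawn relative-refractory
        durations in samples (alternative mode)
    states : (n_trials, 6) initial membrane states, updated in place
    out_t, out_w : (n_trials, max_spikes) spike times / sources
    out_n : (n_trials,) spike counts
    """
    n_trials = noise_per.shape[0]
    empty_i = np.empty(0, dtype=np.int64)
    empty_f = np.zeros(1, dtype=np.float64)
    for k in range(n_trials):
        if rel_offsets.shape[0] > 0:
            rel_k = rel_idx_flat[rel_offsets[k]:rel_offsets[k + 1]]
            draws_k = rrp_draw_steps[k]
        else:
            rel_k = empty_i
            draws_k = empty_f
        syn_k = syn_per[k] if syn_per.shape[0] > 0 else empty_f[:0]
        out_n[k] = _integrate_trial(
            p, elec_per, elec_cen, syn_k, noise_per[k], noise_cen[k],
            rel_k, draws_k, states[k], out_t[k], out_w[k])


def make_param_vector(fiber, per, cen, dt: float) -> np.ndarray:
    """Assemble the kernel parameter vector for one fiber.

    ``per`` and ``cen`` are the :class:`~easfiber.population.ESNeuronConstants`
    of the two neurons; per-fiber values (capacitances, scaled
    suprathreshold time constants, dead time) come from ``fiber``.
    """
    p = np.empty(19)
    p[0] = dt
    p[1] = per.E_L
    p[2] = per.v_thr
    p[3] = per.v_peak
    p[4] = per.v_reset
    p[5] = per.tau_sub
    p[6] = per.a_sub
    p[7] = per.a_supra
    p[8] = per.b
    p[9] = fiber.C_per
    p[10] = fiber.C_cen
    p[11] = per.g_L
    p[12] = cen.g_L
    p[13] = per.Delta_T
    p[14] = cen.Delta_T
    p[15] = fiber.tau_supra_per
    p[16] = fiber.tau_supra_cen
    p[17] = round(fiber.t_dead / dt)
    p[18] = round(fiber.t_abs / dt)
    return p
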