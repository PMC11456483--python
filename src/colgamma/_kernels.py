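"""Numba-compiled inner loops for the forward-Euler integrators.

These kernels replicate the vectorised right-hand sides in
:mod:`colgamma.model_core` (mean field) and the per-neuron voltage equation
(microscopic network); the test suite checks step-for-step agreement with
the pure-numpy reference path.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# Status codes returned by the kernels.
OK = 0
NONFINITE = 1       # NaN/Inf or rate above the sanity ceiling
NEGATIVE = 2        # positivity violation (r < 0 or g < 0)
STEP_WARNING = 3    # substep guard hit its cap (under-resolved spike)


@njit(cache=True)
def _mf_deriv(r, v, ge, gi, zeta, eta, kappa, C, delta,
              A_exc, A_inh, I_ext, tau_e, tau_i, v_syn_e, v_syn_i,
              dr, dv, dge, dgi):
    n = r.shape[0]
    pi = np.pi
    drive_e = A_exc @ r
    drive_i = A_inh @ r
    for j in range(n):
        gsum = ge[j] + gi[j]
        dr[j] = (2.0 * zeta[j] * r[j] * v[j] + eta[j] * r[j]
                 - r[j] * gsum / C[j] + zeta[j] * delta[j] / (pi * C[j]))
        dv[j] = (zeta[j] * v[j] * v[j] + eta[j] * v[j] + kappa[j]
                 - (pi * pi / zeta[j]) * r[j] * r[j]
                 + (ge[j] * v_syn_e + gi[j] * v_syn_i - v[j] * gsum) / C[j]
                 + I_ext[j])
        dge[j] = -ge[j] / tau_e + drive_e[j]
        dgi[j] = -gi[j] / tau_i + drive_i[j]


@njit(cache=True)
def euler_mean_field(
    r, v, ge, gi,
    zeta, eta, kappa, C, delta,
    A_exc, A_inh,
    I_pre, I_post,
    dt, n_steps, onset_step, stride,
    r_ceiling, tau_e, tau_i, v_syn_e, v_syn_i,
    dv_max=0.5, dr_rel_max=0.2, h_min_frac=1e-7,
):
    """Integrate the mean-field system, recording every ``stride`` steps.

    Forward Euler on the nominal grid.  Within a grid step the advance is
    locally adaptive: no sub-advance may move a voltage by more than
    ``dv_max`` (mV) or remove more than ``dr_rel_max`` of a population's
    remaining rate (which keeps r positive through spike troughs); the
    local step never falls below ``h_min_frac * dt``.  Outside the brief
    near-singular synchronous spikes the guard never engages and the map
    is plain fixed-step Euler.

    Returns ``(r_rec, v_rec, status, bad_pop, bad_step)``; on a nonzero
    fatal status the recorded arrays are valid up to ``bad_step // stride``.
    """
    n = r.shape[0]
    n_rec = n_steps // stride + 1
    r_rec = np.empty((n_rec, n))
    v_rec = np.empty((n_rec, n))
    for j in range(n):
        r_rec[0, j] = r[j]
        v_rec[0, j] = v[j]
    dr = np.empty(n)
    dv = np.empty(n)
    dge = np.empty(n)
    dgi = np.empty(n)
    status = OK
    bad_pop = -1
    bad_step = -1
    capped = False
    h_min = h_min_frac * dt
    for step in range(1, n_steps + 1):
        I_ext = I_post if (step - 1) >= onset_step else I_pre
        _mf_deriv(r, v, ge, gi, zeta, eta, kappa, C, delta,
                  A_exc, A_inh, I_ext, tau_e, tau_i, v_syn_e, v_syn_i,
                  dr, dv, dge, dgi)
        adv = 0.0
        first = True
        while True:
            if not first:
                _mf_deriv(r, v, ge, gi, zeta, eta, kappa, C, delta,
                          A_exc, A_inh, I_ext, tau_e, tau_i,
                          v_syn_e, v_syn_i, dr, dv, dge, dgi)
            first = False
            h = dt - adv
            for j in range(n):
                av = abs(dv[j])
                if av * h > dv_max:
                    h = dv_max / av
                if dr[j] < 0.0:
                    # never let a step remove more than dr_rel_max of the
                    # remaining rate: keeps r positive through spike troughs
                    hr = dr_rel_max * (r[j] + 1e-12) / (-dr[j])
                    if hr < h:
                        h = hr
            if h < h_min:
                h = h_min
                capped = True
            if adv + h >= dt:
                h = dt - adv
                adv = dt
            else:
                adv += h
            for j in range(n):
                r[j] = r[j] + h * dr[j]
                v[j] = v[j] + h * dv[j]
                ge[j] = ge[j] + h * dge[j]
                gi[j] = gi[j] + h * dgi[j]
            if adv >= dt:
                break
        if step % stride == 0:
            kk = step // stride
            for j in range(n):
                r_rec[kk, j] = r[j]
                v_rec[kk, j] = v[j]
                if status == OK:
                    if (not np.isfinite(r[j])) or (not np.isfinite(v[j])) \
                            or (not np.isfinite(ge[j])) or (not np.isfinite(gi[j])) \
                            or r[j] > r_ceiling:
                        status = NONFINITE
                        bad_pop = j
                        bad_step = step
                    elif r[j] < 0.0 or ge[j] < 0.0 or gi[j] < 0.0:
                        status = NEGATIVE
                        bad_pop = j
                        bad_step = step
            if status != OK:
                return r_rec[: kk + 1], v_rec[: kk + 1], status, bad_pop, bad_step
    if capped and status == OK:
        status = STEP_WARNING
    return r_rec, v_rec, status, bad_pop, bad_step


@njit(cache=True)
def euler_micro(
    V, ge, gi, I_const,
    zeta, eta, kappa, C_inv,
    conn_indptr, conn_targets, conn_weights,
    is_exc_source,
    neuron_pop,
    dt, n_steps, onset_step,
    I_pre_pop, I_post_pop,
    V_peak, V_reset, tau_e, tau_i,
    v_syn_e, v_syn_i,
    bin_steps, n_pops, pop_counts,
):
    """Integrate the finite-N spiking QIF network.

    Per-neuron states: voltage ``V`` and received conductances ``ge``/``gi``.
    ``conn_indptr``/``conn_targets``/``conn_weights`` give each source
    neuron's postsynaptic targets and increment sizes (CSR layout); a spike
    adds the connection weight to the appropriate conductance of each
    target.  Returns spike times/ids and per-population binned rates
    (spikes / (N * bin)).
    """
    n = V.shape[0]
    n_bins = n_steps // bin_steps
    rate_bins = np.zeros((n_bins, n_pops))
    max_spikes = 64
    spike_times = np.empty(max_spikes)
    spike_ids = np.empty(max_spikes, dtype=np.int64)
    n_spikes = 0
    status = OK
    for step in range(1, n_steps + 1):
        ext_on = (step - 1) >= onset_step
        for i in range(n):
            p = neuron_pop[i]
            I_ext = I_post_pop[p] if ext_on else I_pre_pop[p]
            # zeta/eta/kappa already carry the 1/C factor; synaptic currents
            # and external drives are divided by C explicitly.
            V[i] = V[i] + dt * (zeta[p] * V[i] * V[i] + eta[p] * V[i] + kappa[p]
                                + C_inv[p] * (-ge[i] * (V[i] - v_syn_e)
                                              - gi[i] * (V[i] - v_syn_i)
                                              + I_const[i] + I_ext))
        # conductance decay
        decay_e = 1.0 - dt / tau_e
        decay_i = 1.0 - dt / tau_i
        for i in range(n):
            ge[i] *= decay_e
            gi[i] *= decay_i
        # spike detection and propagation
        for i in range(n):
            if V[i] >= V_peak:
                V[i] = V_reset
                if n_spikes >= max_spikes:
                    new_cap = max_spikes * 2
                    new_times = np.empty(new_cap)
                    new_ids = np.empty(new_cap, dtype=np.int64)
                    for s in range(n_spikes):
                        new_times[s] = spike_times[s]
                        new_ids[s] = spike_ids[s]
                    spike_times = new_times
                    spike_ids = new_ids
                    max_spikes = new_cap
                spike_times[n_spikes] = step * dt
                spike_ids[n_spikes] = i
                n_spikes += 1
                b = (step - 1) // bin_steps
                if b < n_bins:
                    rate_bins[b, neuron_pop[i]] += 1.0
                if is_exc_source[i]:
                    for k in range(conn_indptr[i], conn_indptr[i + 1]):
                        ge[conn_targets[k]] += conn_weights[k]
                else:
                    for k in range(conn_indptr[i], conn_indptr[i + 1]):
                        gi[conn_targets[k]] += conn_weights[k]
            elif not np.isfinite(V[i]):
                status = NONFINITE
                return spike_times[:n_spikes], spike_ids[:n_spikes], rate_bins, status, step
    bin_ms = bin_steps * dt
    for b in range(n_bins):
        for p in range(n_pops):
            rate_bins[b, p] /= pop_counts[p] * bin_ms
    return spike_times[:n_spikes], spike_ids[:n_spikes], rate_bins, status, n_steps
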