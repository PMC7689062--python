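"""Compiled inner loop for one image presentation.

This mirrors, operation for operation, the reference path built from
:func:`snnprune.neuro.step_neurons`, :func:`snnprune.neuro.decay_traces`,
and the STDP spike handlers; the test suite checks agreement between the
two routes.  The kernel exists purely for speed — the clock-driven loop
over sub-millisecond steps dominates the runtime of every experiment.
"""

from __future__ import annotations

import numpy as np
from numba import njit

from .neuro import ACTIVE, REMOVED


@njit(cache=True)
def present_kernel(
    w,  # (n_in, n_exc) float64, modified in place when plastic
    status,  # (n_in, n_exc) int8
    v_e, ge_e, gi_e, theta_e, refrac_e,  # excitatory state, in place
    v_i, ge_i, gi_i, refrac_i,  # inhibitory state, in place
    x, y1, y2,  # STDP traces, in place
    pending_exc, pending_inh,  # (n,) bool, one-step-delay buffers, in place
    input_spikes,  # (n_present, n_in) bool
    n_rest: int,
    dt: float,
    tau_m: float, v_r: float, v_th: float, E_exc: float, E_inh: float,
    decay_ge: float, decay_gi: float,
    theta_plus: float, decay_theta: float, t_refrac: float,
    decay_x: float, decay_y1: float, decay_y2: float,
    mu_pre: float, mu_post: float, w_max: float,
    w_exc_inh: float, w_inh_exc: float,
    plastic: bool,
    track_dw: bool,
):
    n_in, n_exc = w.shape
    n_present = input_spikes.shape[0]
    counts = np.zeros(n_exc, dtype=np.int64)
    exc_drive = np.zeros(n_exc)
    inh_drive = np.zeros(n_exc)
    inh_exc_drive = np.zeros(n_exc)
    spk_rows = np.empty(n_in, dtype=np.intp)
    # SOP counters: accum, stdp_pre, stdp_post, exc->inh, inh->exc events
    sops = np.zeros(5, dtype=np.int64)
    dw_count = 0
    dw_total = 0.0
    dw_total_sq = 0.0

    for step in range(n_present + n_rest):
        # ---- spike delivery (input this step; recurrent from last step) ----
        n_rows = 0
        for i in range(n_exc):
            exc_drive[i] = 0.0
        if step < n_present:
            for j in range(n_in):
                if input_spikes[step, j]:
                    spk_rows[n_rows] = j
                    n_rows += 1
                    for i in range(n_exc):
                        if status[j, i] != REMOVED:
                            exc_drive[i] += w[j, i]
                            sops[0] += 1
        k_inh = 0
        for i in range(n_exc):
            if pending_inh[i]:
                k_inh += 1
        for i in range(n_exc):
            if k_inh:
                inh_drive[i] = w_inh_exc * (k_inh - (1.0 if pending_inh[i] else 0.0))
            else:
                inh_drive[i] = 0.0
            inh_exc_drive[i] = w_exc_inh if pending_exc[i] else 0.0
            if pending_exc[i]:
                sops[3] += 1
        if k_inh:
            sops[4] += k_inh * (n_exc - 1)

        # ---- excitatory neurons -------------------------------------------
        for i in range(n_exc):
            ge_e[i] = ge_e[i] * decay_ge + exc_drive[i]
            gi_e[i] = gi_e[i] * decay_gi + inh_drive[i]
            refractory = refrac_e[i] > 0.0
            if not refractory:
                dv = (
                    (v_r - v_e[i])
                    - ge_e[i] * (v_e[i] - E_exc)
                    - gi_e[i] * (v_e[i] - E_inh)
                ) * (dt / tau_m)
                v_e[i] = v_e[i] + dv
            spiked = (not refractory) and v_e[i] >= v_th + theta_e[i]
            if spiked:
                v_e[i] = v_r
                if plastic:
                    theta_e[i] += theta_plus
                refrac_e[i] = t_refrac
                counts[i] += 1
            if plastic:
                theta_e[i] *= decay_theta
            refrac_e[i] = max(refrac_e[i] - dt, 0.0)
            pending_exc[i] = spiked

        # ---- inhibitory neurons (no threshold adaptation) -----------------
        for i in range(n_exc):
            ge_i[i] = ge_i[i] * decay_ge + inh_exc_drive[i]
            gi_i[i] = gi_i[i] * decay_gi
            refractory = refrac_i[i] > 0.0
            if not refractory:
                dv = (
                    (v_r - v_i[i])
                    - ge_i[i] * (v_i[i] - E_exc)
                    - gi_i[i] * (v_i[i] - E_inh)
                ) * (dt / tau_m)
                v_i[i] = v_i[i] + dv
            spiked = (not refractory) and v_i[i] >= v_th
            if spiked:
                v_i[i] = v_r
                refrac_i[i] = t_refrac
            refrac_i[i] = max(refrac_i[i] - dt, 0.0)
            pending_inh[i] = spiked

        # ---- plasticity ----------------------------------------------------
        if plastic:
            for j in range(n_in):
                x[j] *= decay_x
            for i in range(n_exc):
                y1[i] *= decay_y1
                y2[i] *= decay_y2
            # depression on presynaptic spikes, then x reset
            for r in range(n_rows):
                j = spk_rows[r]
                for i in range(n_exc):
                    if status[j, i] == ACTIVE:
                        old = w[j, i]
                        new = old - mu_pre * y1[i]
                        if new < 0.0:
                            new = 0.0
                        elif new > w_max:
                            new = w_max
                        w[j, i] = new
                        sops[1] += 1
                        if track_dw:
                            dw = new - old
                            dw_count += 1
                            dw_total += dw
                            dw_total_sq += dw * dw
                x[j] = 1.0
            # potentiation on postsynaptic spikes (pre-reset y2), then resets
            for i in range(n_exc):
                if pending_exc[i]:
                    for j in range(n_in):
                        if status[j, i] == ACTIVE:
                            old = w[j, i]
                            new = old + mu_post * x[j] * y2[i]
                            if new < 0.0:
                                new = 0.0
                            elif new > w_max:
                                new = w_max
                            w[j, i] = new
                            sops[2] += 1
                            if track_dw:
                                dw = new - old
                                dw_count += 1
                                dw_total += dw
                                dw_total_sq += dw * dw
                    y1[i] = 1.0
                    y2[i] = 1.0

    return counts, sops, dw_count, dw_total, dw_total_sq
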