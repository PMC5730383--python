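"""Numba-compiled inner loops for the closed-loop spiking simulation.

The per-tick semantics are defined by the pure-numpy ``FollowNetwork.step``;
the kernel here is an optimization of the same update order, verified against
it in the test suite.  The only structural difference is that the plasticity
increment of tick ``t`` is applied lazily, fused into the weight-matrix pass of
tick ``t+1`` (and flushed at snapshots and at the end of the phase), which
halves memory traffic over the weight matrices without changing any value that
the simulation ever reads.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["run_phase_kernel", "readout_learn_kernel"]


@njit(cache=True, fastmath=True)
def run_phase_kernel(
    dt,
    Ecmd, bcmd,              # command-layer weighted encoders (Ncmd,Nc), biases
    Efb, brec,               # error-feedback weighted encoders (N,Nd), biases
    D,                       # decoders (Nd,N)
    wff, wrec,               # plastic weights, modified in place
    use_mask_ff, mask_ff,    # masks as float arrays (1.0/0.0); dummies if unused
    use_mask_rec, mask_rec,
    k_fb, k_learn,           # feedback gain in the current / in the learn trace
    inv_n_ff, inv_n_rec,     # 1/n_pre normalization of the learning rate
    eta_dt,                  # (T,) learning rate * dt per tick; 0 => frozen
    u, xref, noise,          # (T,Nc), (T,Nd) error-node reference, (T,Nd)
    tau_m, tau_r, threshold, v_floor,
    decay_s, tau_s_inv, one_m_decay_s,
    decay_eps, one_m_decay_eps,
    Vc, refc, Vr, refr,      # LIF state, in place
    ctr, rtr, etr, ltr,      # traces, in place
    rec_every, xhat_out, err_out,
    spike_counts_cmd, spike_counts_rec,
    record_spikes, spikes_out,      # uint8 (T,N) raster or (1,1) dummy
    snap_every, wff_snaps, wrec_snaps,
):
    T = u.shape[0]
    Ncmd = Ecmd.shape[0]
    Nc = Ecmd.shape[1]
    N = Efb.shape[0]
    Nd = Efb.shape[1]
    decay_m = np.exp(-dt / tau_m)

    prev_ctr = ctr.copy()
    prev_eta = 0.0
    spikes_rec = np.zeros(N, dtype=wrec.dtype)
    xhat = np.zeros(Nd, dtype=wrec.dtype)
    eps = np.zeros(Nd, dtype=wrec.dtype)

    for t in range(T):
        # (i) command currents and command-layer LIF step
        for l in range(Ncmd):
            J = bcmd[l]
            for a in range(Nc):
                J += Ecmd[l, a] * u[t, a]
            r = refc[l] - dt
            if r < 0.0:
                r = 0.0
            delta = dt - r
            if delta < 0.0:
                delta = 0.0
            v = Vc[l]
            if delta == dt:
                v = J + (v - J) * decay_m
            else:
                v = J + (v - J) * np.exp(-delta / tau_m)
            spike = 0.0
            if v > threshold:
                r = tau_r + dt - tau_m * np.log((J - threshold) / (J - v))
                v = 0.0
                spike = 1.0
                spike_counts_cmd[l] += 1
            if v < v_floor:
                v = v_floor
            Vc[l] = v
            refc[l] = r
            # (ii) command trace update (flush tiny values: denormals are slow)
            tr = ctr[l] * decay_s + spike * tau_s_inv
            ctr[l] = tr if tr > 1e-12 else 0.0

        # (iii) recurrent currents (previous-tick rec/err traces), fused with
        # the pending plasticity increment of the previous tick, then LIF step
        pend = prev_eta > 0.0
        for i in range(N):
            acc = brec[i]
            li_ff = prev_eta * inv_n_ff * ltr[i]
            li_rec = prev_eta * inv_n_rec * ltr[i]
            if pend:
                if use_mask_ff:
                    for l in range(Ncmd):
                        w = wff[i, l] + li_ff * prev_ctr[l] * mask_ff[i, l]
                        wff[i, l] = w
                        acc += w * ctr[l]
                else:
                    for l in range(Ncmd):
                        w = wff[i, l] + li_ff * prev_ctr[l]
                        wff[i, l] = w
                        acc += w * ctr[l]
                if use_mask_rec:
                    for j in range(N):
                        w = wrec[i, j] + li_rec * rtr[j] * mask_rec[i, j]
                        wrec[i, j] = w
                        acc += w * rtr[j]
                else:
                    for j in range(N):
                        w = wrec[i, j] + li_rec * rtr[j]
                        wrec[i, j] = w
                        acc += w * rtr[j]
            else:
                for l in range(Ncmd):
                    acc += wff[i, l] * ctr[l]
                for j in range(N):
                    acc += wrec[i, j] * rtr[j]
            if k_fb != 0.0:
                for a in range(Nd):
                    acc += k_fb * Efb[i, a] * etr[a]

            r = refr[i] - dt
            if r < 0.0:
                r = 0.0
            delta = dt - r
            if delta < 0.0:
                delta = 0.0
            v = Vr[i]
            if delta == dt:
                v = acc + (v - acc) * decay_m
            else:
                v = acc + (v - acc) * np.exp(-delta / tau_m)
            spike = 0.0
            if v > threshold:
                r = tau_r + dt - tau_m * np.log((acc - threshold) / (acc - v))
                v = 0.0
                spike = 1.0
                spike_counts_rec[i] += 1
                if record_spikes:
                    spikes_out[t, i] = 1
            if v < v_floor:
                v = v_floor
            Vr[i] = v
            refr[i] = r
            spikes_rec[i] = spike

        # (iv) recurrent trace update, (v) decode
        for a in range(Nd):
            xhat[a] = 0.0
        for i in range(N):
            tr = rtr[i] * decay_s + spikes_rec[i] * tau_s_inv
            if tr <= 1e-12:
                tr = 0.0
            rtr[i] = tr
            for a in range(Nd):
                xhat[a] += D[a, i] * tr

        # (vi) error, (vii) error traces
        for a in range(Nd):
            eps[a] = xref[t, a] - xhat[a] + noise[t, a]
            etr[a] = etr[a] * decay_s + eps[a] * one_m_decay_s
        for i in range(N):
            ie = 0.0
            for a in range(Nd):
                ie += Efb[i, a] * eps[a]
            lt = ltr[i] * decay_eps + k_learn * ie * one_m_decay_eps
            ltr[i] = lt if (lt > 1e-12 or lt < -1e-12) else 0.0

        if t % rec_every == 0:
            m = t // rec_every
            for a in range(Nd):
                xhat_out[m, a] = xhat[a]
                err_out[m, a] = eps[a]

        # (viii) plasticity of this tick becomes the pending increment
        prev_eta = eta_dt[t]
        if prev_eta > 0.0:
            for l in range(Ncmd):
                prev_ctr[l] = ctr[l]

        if snap_every > 0 and (t + 1) % snap_every == 0:
            if prev_eta > 0.0:
                _apply_update(wff, wrec, ltr, ctr, rtr,
                              prev_eta * inv_n_ff, prev_eta * inv_n_rec,
                              use_mask_ff, mask_ff, use_mask_rec, mask_rec)
                prev_eta = 0.0
            s = (t + 1) // snap_every - 1
            if s < wff_snaps.shape[0]:
                wff_snaps[s] = wff
                wrec_snaps[s] = wrec

    if prev_eta > 0.0:
        _apply_update(wff, wrec, ltr, ctr, rtr,
                      prev_eta * inv_n_ff, prev_eta * inv_n_rec,
                      use_mask_ff, mask_ff, use_mask_rec, mask_rec)


@njit(cache=True)
def _apply_update(wff, wrec, ltr, ctr, rtr, eta_dt_ff, eta_dt_rec,
                  use_mask_ff, mask_ff, use_mask_rec, mask_rec):
    N, Ncmd = wff.shape
    for i in range(N):
        li_ff = eta_dt_ff * ltr[i]
        li_rec = eta_dt_rec * ltr[i]
        if use_mask_ff:
            for l in range(Ncmd):
                wff[i, l] += li_ff * ctr[l] * mask_ff[i, l]
        else:
            for l in range(Ncmd):
                wff[i, l] += li_ff * ctr[l]
        if use_mask_rec:
            for j in range(N):
                wrec[i, j] += li_rec * rtr[j] * mask_rec[i, j]
        else:
            for j in range(N):
                wrec[i, j] += li_rec * rtr[j]


@njit(cache=True)
def readout_learn_kernel(raster, target, d, tau_s, dt, eta_r, err_out, rec_every):
    """Online perceptron learning of readout weights from a recorded raster.

    Reconstructs the filtered spike traces from ``raster`` (T,N uint8) and
    updates ``d`` (Nd,N) in place by
    ``d_ai -= eta_r * (xhat_a - target_a) * trace_i * dt`` each tick.
    Records the output error norm every ``rec_every`` ticks into ``err_out``.
    """
    T, N = raster.shape
    Nd = d.shape[0]
    decay_s = np.exp(-dt / tau_s)
    tau_s_inv = 1.0 / tau_s
    trace = np.zeros(N)
    xhat = np.zeros(Nd)
    for t in range(T):
        for i in range(N):
            tr = trace[i] * decay_s + raster[t, i] * tau_s_inv
            trace[i] = tr if tr > 1e-12 else 0.0
        for a in range(Nd):
            s = 0.0
            for i in range(N):
                s += d[a, i] * trace[i]
            xhat[a] = s
        for a in range(Nd):
            e = eta_r * (xhat[a] - target[t, a]) * dt
            for i in range(N):
                d[a, i] -= e * trace[i]
        if t % rec_every == 0:
            s = 0.0
            for a in range(Nd):
                diff = xhat[a] - target[t, a]
                s += diff * diff
            err_out[t // rec_every] = np.sqrt(s)
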