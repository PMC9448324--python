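"""Numba kernels: the LIF integration loop and a fast all-pairs STTC path.

Everything here works in a fixed unit system (mV, ms, nS, pF, pA) so that
nS * mV = pA and pA * ms / pF = mV hold without conversion factors.
"""

import numpy as np
from numba import njit

__all__ = ["run_lif_kernel", "pairwise_sttc_mean", "tiled_fraction", "coincident_fraction"]


@njit(cache=True)
def run_lif_kernel(
    n_exc,
    v_leak,
    v_thresh,
    v_reset,
    t_ref_steps,
    c_m,
    g_leak,
    g_decay_ampa,
    g_decay_gaba,
    w_ampa,
    w_gaba,
    e_ampa,
    e_gaba,
    g_ext,
    ext_rate_khz,
    ou_sigma,
    ou_decay,
    ou_kick,
    i_const,
    stim,
    stim_mask,
    dt_ms,
    n_steps,
    lfp_decim,
    seed,
    include_ext_in_lfp,
):
    """Integrate the conductance-based LIF network.

    Exponential-Euler decay for conductances and the OU noise current,
    forward-Euler step for the membrane potential. Synaptic transmission is
    instantaneous (zero delay): a spike at step t increments the postsynaptic
    conductances before step t+1. During refractoriness the membrane is
    clamped at v_reset while conductances keep evolving.

    The external Poisson pool is shared: every excitatory unit receives the
    same pooled spike count each step (tracked as one scalar conductance,
    all excitatory units share tau_ampa).

    Returns (spike_steps, spike_units, lfp, error_step). error_step is -1 on
    success, else the first step at which a non-finite membrane potential
    was observed.
    """
    np.random.seed(seed)
    n = v_leak.shape[0]
    n_lfp = n_steps // lfp_decim

    vm = v_leak.copy()
    g_a = np.zeros(n)
    g_g = np.zeros(n)
    g_ext_shared = 0.0
    eta = np.zeros(n)
    ref = np.zeros(n, dtype=np.int64)

    lfp = np.zeros(n_lfp)

    cap = 65536
    spk_step = np.empty(cap, dtype=np.int64)
    spk_unit = np.empty(cap, dtype=np.int32)
    n_spk = 0

    ext_mean = ext_rate_khz * dt_ms  # expected shared pool spikes per step
    exc_ampa_decay = g_decay_ampa[0]
    has_stim = stim.shape[0] > 0

    for step in range(n_steps):
        # conductance + noise decay (exact for the linear ODEs)
        for i in range(n):
            g_a[i] *= g_decay_ampa[i]
            g_g[i] *= g_decay_gaba[i]
            eta[i] = ou_decay * eta[i] + ou_kick * ou_sigma * np.random.normal(0.0, 1.0)
        g_ext_shared *= exc_ampa_decay

        # shared external Poisson drive onto excitatory units
        if ext_mean > 0.0:
            n_ext = np.random.poisson(ext_mean)
            if n_ext > 0:
                g_ext_shared += n_ext * g_ext

        stim_now = stim[step] if has_stim else 0.0

        bin_idx = step // lfp_decim
        for i in range(n):
            ge = g_a[i] + g_ext_shared if i < n_exc else g_a[i]
            i_ampa = ge * (vm[i] - e_ampa)
            i_gaba = g_g[i] * (vm[i] - e_gaba)
            if i < n_exc:
                if include_ext_in_lfp:
                    lfp[bin_idx] += abs(i_ampa) + abs(i_gaba)
                else:
                    lfp[bin_idx] += abs(g_a[i] * (vm[i] - e_ampa)) + abs(i_gaba)
            if ref[i] > 0:
                ref[i] -= 1
                vm[i] = v_reset[i]
                continue
            i_total = (
                -g_leak[i] * (vm[i] - v_leak[i])
                - i_ampa
                - i_gaba
                + eta[i]
                + i_const[i]
            )
            if stim_now != 0.0 and stim_mask[i]:
                i_total += stim_now
            vm[i] += dt_ms * i_total / c_m[i]

        # threshold crossings: record, reset, propagate instantaneously
        for i in range(n):
            if ref[i] == 0 and vm[i] >= v_thresh[i]:
                if n_spk == cap:
                    cap *= 2
                    tmp_s = np.empty(cap, dtype=np.int64)
                    tmp_u = np.empty(cap, dtype=np.int32)
                    tmp_s[:n_spk] = spk_step
                    tmp_u[:n_spk] = spk_unit
                    spk_step = tmp_s
                    spk_unit = tmp_u
                spk_step[n_spk] = step
                spk_unit[n_spk] = i
                n_spk += 1
                vm[i] = v_reset[i]
                ref[i] = t_ref_steps[i]
                if i < n_exc:
                    row = w_ampa[i]
                    for j in range(n):
                        g_a[j] += row[j]
                else:
                    row = w_gaba[i - n_exc]
                    for j in range(n):
                        g_g[j] += row[j]

        if (step + 1) % lfp_decim == 0:
            s = 0.0
            for i in range(n):
                s += vm[i]
            if not np.isfinite(s):
                return spk_step[:n_spk], spk_unit[:n_spk], lfp, step

    for b in range(n_lfp):
        lfp[b] /= lfp_decim
    return spk_step[:n_spk], spk_unit[:n_spk], lfp, -1


@njit(cache=True)
def tiled_fraction(times, duration, lag):
    """Fraction of [0, duration) covered by the union of [t-lag, t+lag]."""
    total = 0.0
    prev_end = 0.0
    for k in range(times.shape[0]):
        lo = times[k] - lag
        hi = times[k] + lag
        if lo < 0.0:
            lo = 0.0
        if hi > duration:
            hi = duration
        if lo < prev_end:
            lo = prev_end
        if hi > lo:
            total += hi - lo
            prev_end = hi
        elif hi > prev_end:
            prev_end = hi
    return total / duration


@njit(cache=True)
def coincident_fraction(a, b, lag):
    """Fraction of spikes in a within +-lag (inclusive) of any spike in b."""
    na = a.shape[0]
    nb = b.shape[0]
    if na == 0 or nb == 0:
        return 0.0
    count = 0
    j = 0
    for i in range(na):
        while j < nb and b[j] < a[i] - lag:
            j += 1
        if j < nb and b[j] <= a[i] + lag:
            count += 1
    return count / na


@njit(cache=True)
def pairwise_sttc_mean(times, offsets, duration, lag, min_spikes):
    """Mean STTC over all unit pairs with at least min_spikes spikes each.

    times: concatenated sorted spike times; offsets[u]:offsets[u+1] indexes
    unit u. Pairs with an undefined STTC (degenerate denominator) are
    skipped. Returns (mean, n_pairs_used).
    """
    n_units = offsets.shape[0] - 1
    tiled = np.empty(n_units)
    ok = np.zeros(n_units, dtype=np.bool_)
    for u in range(n_units):
        lo, hi = offsets[u], offsets[u + 1]
        if hi - lo >= min_spikes and hi - lo > 0:
            ok[u] = True
            tiled[u] = tiled_fraction(times[lo:hi], duration, lag)
    total = 0.0
    n_pairs = 0
    for u in range(n_units):
        if not ok[u]:
            continue
        a = times[offsets[u]:offsets[u + 1]]
        for v in range(u + 1, n_units):
            if not ok[v]:
                continue
            b = times[offsets[v]:offsets[v + 1]]
            pa = coincident_fraction(a, b, lag)
            pb = coincident_fraction(b, a, lag)
            da = 1.0 - pa * tiled[v]
            db = 1.0 - pb * tiled[u]
            if da == 0.0 or db == 0.0:
                continue
            total += 0.5 * ((pa - tiled[v]) / da + (pb - tiled[u]) / db)
            n_pairs += 1
    if n_pairs == 0:
        return np.nan, 0
    return total / n_pairs, n_pairs
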