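"""Independent oracles used by the test suite.

The brute-force STTC below shares no code with the package: tiling is
computed by merging sorted interval endpoints, coincidences by exhaustive
pairwise comparison.
"""

import numpy as np


def brute_force_tiled_fraction(times, duration, lag):
    """Union length of +-lag windows via explicit interval merging."""
    intervals = sorted(
        (max(0.0, t - lag), min(duration, t + lag)) for t in np.asarray(times)
    )
    total = 0.0
    cur_lo, cur_hi = None, None
    for lo, hi in intervals:
        if cur_hi is None:
            cur_lo, cur_hi = lo, hi
        elif lo <= cur_hi:
            cur_hi = max(cur_hi, hi)
        else:
            total += cur_hi - cur_lo
            cur_lo, cur_hi = lo, hi
    if cur_hi is not None:
        total += cur_hi - cur_lo
    return total / duration


def brute_force_sttc(a, b, duration, lag):
    """Exhaustive-evaluation spike time tiling coefficient."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        return np.nan
    pa = np.mean([np.any(np.abs(b - t) <= lag) for t in a])
    pb = np.mean([np.any(np.abs(a - t) <= lag) for t in b])
    ta = brute_force_tiled_fraction(a, duration, lag)
    tb = brute_force_tiled_fraction(b, duration, lag)
    da, db = 1.0 - pa * tb, 1.0 - pb * ta
    if da == 0.0 or db == 0.0:
        return np.nan
    return 0.5 * ((pa - tb) / da + (pb - ta) / db)


def analytic_lif_first_spike_ms(i_const_pa, params):
    """Closed-form time to first spike of a leak-only LIF under constant
    current, starting from the leak potential. Returns np.inf if the
    current cannot reach threshold."""
    drive = i_const_pa / params.g_leak  # mV above v_leak at steady state
    gap = params.v_thresh - params.v_leak
    if drive <= gap:
        return np.inf
    return -params.tau_m * np.log(1.0 - gap / drive)
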