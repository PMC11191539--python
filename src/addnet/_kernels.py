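"""Inner integration loop for the coupled neural-mass network.

The loop is written as a plain Python function with explicit indexing so it
can be compiled with numba when available; the uncompiled function serves as
a slow but exact fallback (same operations, same order, bit-identical
results with ``fastmath`` disabled).
"""

from __future__ import annotations

import math

import numpy as np

__all__ = ["epoch_loop", "HAVE_NUMBA"]


def _epoch_loop(
    adj,
    n_samples,
    n_transient,
    substeps,
    h,
    da1,
    db1,
    k1,
    da2,
    db2,
    k2,
    pt,
    sigma,
    gmax,
    q,
    vd1,
    vd2,
    c1,
    c2,
    s_coup,
    add_on,
    d_eff,
    floor,
    noise,
    sa_te,
    sb_te,
    sa_ie,
    sb_ie,
    sa_ei,
    sb_ei,
    e_rate,
    i_rate,
    ve_cur,
    w_th,
    w_net,
    w_ie,
    w_ei,
    hist,
    hist_len,
    hist_pos,
    sig_out,
    e_out,
    i_out,
):
    n = adj.shape[0]
    win = hist.shape[0]
    idx = 0
    coup = np.empty(n)
    for samp in range(n_samples):
        for _sub in range(substeps):
            # excitatory inter-mass coupling from previous-step spike densities
            for i in range(n):
                acc = 0.0
                for j in range(n):
                    acc += adj[i, j] * w_net[j] * e_rate[j]
                coup[i] = acc
            for i in range(n):
                p_in = pt + sigma * noise[idx, i]
                if p_in < 0.0:
                    p_in = 0.0
                u_te = w_th[i] * p_in + s_coup * w_net[i] * coup[i]
                u_ie = c2 * w_ie[i] * i_rate[i]
                u_ei = c1 * w_ei[i] * e_rate[i]
                sa_te[i] = da1 * sa_te[i] + h * u_te
                sb_te[i] = db1 * sb_te[i] + h * u_te
                sa_ie[i] = da2 * sa_ie[i] + h * u_ie
                sb_ie[i] = db2 * sb_ie[i] + h * u_ie
                sa_ei[i] = da1 * sa_ei[i] + h * u_ei
                sb_ei[i] = db1 * sb_ei[i] + h * u_ei
                ve = k1 * (sa_te[i] - sb_te[i]) - k2 * (sa_ie[i] - sb_ie[i])
                vi = k1 * (sa_ei[i] - sb_ei[i])
                e_rate[i] = gmax / (1.0 + math.exp(q * (vd1 - ve)))
                i_rate[i] = gmax / (1.0 + math.exp(q * (vd2 - vi)))
                ve_cur[i] = ve
            idx += 1
        # end of one 2-ms model sample
        for i in range(n):
            if not math.isfinite(ve_cur[i]):
                return hist_len, hist_pos, samp, i
            hist[hist_pos, i] = e_rate[i]
        hist_pos = (hist_pos + 1) % win
        if hist_len < win:
            hist_len += 1
        if add_on:
            for i in range(n):
                mx = hist[0, i]
                for t in range(1, hist_len):
                    if hist[t, i] > mx:
                        mx = hist[t, i]
                loss = math.exp(-d_eff * mx)
                w_th[i] *= loss
                w_net[i] *= loss
                w_ie[i] *= loss
                w_ei[i] *= loss
                if w_th[i] < floor:
                    w_th[i] = floor
                if w_net[i] < floor:
                    w_net[i] = floor
                if w_ie[i] < floor:
                    w_ie[i] = floor
                if w_ei[i] < floor:
                    w_ei[i] = floor
        if samp >= n_transient:
            r = samp - n_transient
            for i in range(n):
                sig_out[r, i] = ve_cur[i]
                e_out[r, i] = e_rate[i]
                i_out[r, i] = i_rate[i]
    return hist_len, hist_pos, -1, -1


try:  # pragma: no cover - exercised indirectly
    import numba

    epoch_loop = numba.njit(_epoch_loop, fastmath=False, nogil=True)
    HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    epoch_loop = _epoch_loop
    HAVE_NUMBA = False
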