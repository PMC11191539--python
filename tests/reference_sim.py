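"""Independent vectorized reference integrator used as an oracle in tests.

Deliberately written with numpy matrix operations (rather than the explicit
per-mass loops of the production kernel) so that agreement between the two is
meaningful.
"""

import numpy as np


def reference_run(
    net,
    params,
    add,
    noise,
    n_samples,
    n_transient,
    add_enabled=True,
    loss_timing="post",
):
    """Integrate ``n_samples`` model samples; returns (signals, e, i, strengths).

    ``noise``: (n_samples * substeps, n) standard normals.
    ``loss_timing``: 'post' applies the degeneration update after the sigmoid
    update of the sample (production behaviour); 'pre' applies it before.
    """
    adj = np.asarray(net.adjacency, dtype=float)
    n = adj.shape[0]
    p = params
    h = p.dt / p.substeps
    k1 = p.amp1 if p.psp_normalization == "raw" else _peak_gain(p.amp1, p.a1, p.b1)
    k2 = p.amp2 if p.psp_normalization == "raw" else _peak_gain(p.amp2, p.a2, p.b2)
    da1, db1 = np.exp(-p.a1 * h), np.exp(-p.b1 * h)
    da2, db2 = np.exp(-p.a2 * h), np.exp(-p.b2 * h)
    sigma = p.sigma * np.sqrt(p.substeps)
    gmax = 2.0 * p.g

    sa_te = np.zeros(n); sb_te = np.zeros(n)
    sa_ie = np.zeros(n); sb_ie = np.zeros(n)
    sa_ei = np.zeros(n); sb_ei = np.zeros(n)
    e = np.zeros(n); i = np.zeros(n); ve = np.zeros(n)
    w = {k: np.ones(n) for k in ("th", "net", "ie", "ei")}
    hist = []

    def sigmoid(v, vd):
        return gmax / (1.0 + np.exp(p.q * (vd - v)))

    def degenerate():
        window = np.array(hist[-add.window:])
        loss = np.exp(-add.d_eff * window.max(axis=0))
        for key in w:
            w[key] = np.maximum(w[key] * loss, add.floor)

    n_ret = n_samples - n_transient
    sig = np.zeros((n_ret, n)); e_out = np.zeros((n_ret, n)); i_out = np.zeros((n_ret, n))
    idx = 0
    for samp in range(n_samples):
        if add_enabled and loss_timing == "pre" and hist:
            degenerate()
        for _ in range(p.substeps):
            p_in = np.maximum(p.pt + sigma * noise[idx], 0.0)
            u_te = w["th"] * p_in + p.s * w["net"] * (adj @ (w["net"] * e))
            u_ie = p.c2 * w["ie"] * i
            u_ei = p.c1 * w["ei"] * e
            sa_te = da1 * sa_te + h * u_te; sb_te = db1 * sb_te + h * u_te
            sa_ie = da2 * sa_ie + h * u_ie; sb_ie = db2 * sb_ie + h * u_ie
            sa_ei = da1 * sa_ei + h * u_ei; sb_ei = db1 * sb_ei + h * u_ei
            ve = k1 * (sa_te - sb_te) - k2 * (sa_ie - sb_ie)
            vi = k1 * (sa_ei - sb_ei)
            e = sigmoid(ve, p.vd1)
            i = sigmoid(vi, p.vd2)
            idx += 1
        hist.append(e.copy())
        if add_enabled and loss_timing == "post":
            degenerate()
        if samp >= n_transient:
            r = samp - n_transient
            sig[r] = ve; e_out[r] = e; i_out[r] = i
    return sig, e_out, i_out, w


def _peak_gain(amp, a, b):
    t = np.log(b / a) / (b - a)
    return amp / (np.exp(-a * t) - np.exp(-b * t))
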