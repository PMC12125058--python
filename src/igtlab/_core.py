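"""Numba-compiled batched likelihood kernels.

Hot path for hierarchical fitting: evaluate pointwise log-likelihoods
for many (parameter vector, subject) pairs at once.  ``sub`` maps each
parameter row to its subject's data row, so a batch of M latent vectors
x N subjects never materializes tiled data.  Inputs are already on the
model scale (outcomes rescaled by the caller).
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def _orl_pointwise(params, sub, choices, gains, losses, out):
    B = params.shape[0]
    T = choices.shape[1]
    for b in range(B):
        n = sub[b]
        a_rew = params[b, 0]
        a_pun = params[b, 1]
        K1 = 3.0 ** params[b, 2]  # 1 + K
        bf = params[b, 3]
        bp = params[b, 4]
        ev = np.zeros(4)
        ef = np.zeros(4)
        ps = np.zeros(4)
        for t in range(T):
            j = choices[n, t]
            # log softmax of V at the pre-trial state
            vmax = -1e308
            v = np.empty(4)
            for d in range(4):
                v[d] = ev[d] + ef[d] * bf + ps[d] * bp
                if v[d] > vmax:
                    vmax = v[d]
            z = 0.0
            for d in range(4):
                z += np.exp(v[d] - vmax)
            out[b, t] = v[j] - vmax - np.log(z)
            # update with the observed outcome
            net = gains[n, t] - losses[n, t]
            rate = a_rew if net >= 0.0 else a_pun
            s = 0.0
            if net > 0.0:
                s = 1.0
            elif net < 0.0:
                s = -1.0
            ev[j] += rate * (net - ev[j])
            for d in range(4):
                target = s if d == j else -s / 3.0
                ef[d] += rate * (target - ef[d])
            for d in range(4):
                ps[d] /= K1
            ps[j] = 1.0 / K1


@njit(cache=True)
def _vse_pointwise(params, sub, choices, gains, losses, out):
    B = params.shape[0]
    T = choices.shape[1]
    for b in range(B):
        n = sub[b]
        theta = params[b, 0]
        delta = params[b, 1]
        alpha = params[b, 2]
        phi = params[b, 3]
        c = 3.0 ** params[b, 4] - 1.0
        exploit = np.zeros(4)
        explore = np.zeros(4)
        for t in range(T):
            j = choices[n, t]
            wmax = -1e308
            w = np.empty(4)
            for d in range(4):
                w[d] = (explore[d] + exploit[d]) * c
                if w[d] > wmax:
                    wmax = w[d]
            z = 0.0
            for d in range(4):
                z += np.exp(w[d] - wmax)
            out[b, t] = w[j] - wmax - np.log(z)
            v = gains[n, t] ** theta - losses[n, t] ** theta
            for d in range(4):
                exploit[d] *= delta
            exploit[j] += v
            for d in range(4):
                explore[d] += alpha * (phi - explore[d])
            explore[j] = 0.0


def pointwise_loglik(model, params, choices, gains, losses, sub=None):
    """Pointwise log-likelihood matrix of shape (B, T).

    ``params`` is (B, 5) on natural scales; ``gains``/``losses`` are
    already multiplied by the outcome scale.  ``sub`` (B,) maps each
    parameter row to a data row; by default row ``b`` uses data row
    ``b`` (which then requires ``len(choices) == B``).
    """
    params = np.ascontiguousarray(params, dtype=np.float64)
    choices = np.ascontiguousarray(choices, dtype=np.int64)
    gains = np.ascontiguousarray(gains, dtype=np.float64)
    losses = np.ascontiguousarray(losses, dtype=np.float64)
    B = params.shape[0]
    if sub is None:
        if choices.shape[0] != B:
            raise ValueError("without sub, need one data row per parameter row")
        sub = np.arange(B, dtype=np.int64)
    else:
        sub = np.ascontiguousarray(sub, dtype=np.int64)
    out = np.empty((B, choices.shape[1]), dtype=np.float64)
    if model == "ORL":
        _orl_pointwise(params, sub, choices, gains, losses, out)
    elif model == "VSE":
        _vse_pointwise(params, sub, choices, gains, losses, out)
    else:
        raise ValueError(f"unknown model {model!r}")
    return out
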