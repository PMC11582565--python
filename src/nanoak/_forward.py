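"""Numerical kernels: scaled forward recursion and exact CTMC path sampling."""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=False)
def forward_scan(gamma, logdens, delta):
    """Scaled forward recursion for L = delta' (prod_t Gamma diag(phi_t)) 1.

    The transition matrix is applied before every emission, including the
    first.  Emission densities enter as logs and are rescaled per step by
    their maximum, so the recursion is immune to underflow even for samples
    far in the Gaussian tails.

    Returns (loglik, log_scale[t], filtered[t, m]) where log_scale[t] is the
    log of the per-step normalization constant and filtered[t] the normalized
    forward vector (filtered state probabilities).
    """
    T, n = logdens.shape
    alpha = delta.copy()
    log_scale = np.empty(T)
    filtered = np.empty((T, n))
    loglik = 0.0
    for t in range(T):
        prop = np.zeros(n)
        for j in range(n):
            a = 0.0
            for i in range(n):
                a += alpha[i] * gamma[i, j]
            prop[j] = a
        m = logdens[t, 0]
        for j in range(1, n):
            if logdens[t, j] > m:
                m = logdens[t, j]
        s = 0.0
        for j in range(n):
            prop[j] *= np.exp(logdens[t, j] - m)
            s += prop[j]
        if s <= 0.0 or not np.isfinite(s):
            return -np.inf, log_scale, filtered
        for j in range(n):
            alpha[j] = prop[j] / s
            filtered[t, j] = alpha[j]
        log_scale[t] = np.log(s) + m
        loglik += log_scale[t]
    return loglik, log_scale, filtered


@njit(cache=False)
def gillespie(q_off_cum, exit_rates, init_state, duration_ms, seed):
    """Exact CTMC sample path: exponential sojourns, jumps ~ off-diagonal rates.

    q_off_cum[i] is the cumulative sum of row i's off-diagonal rates (own
    column set to 0); exit_rates[i] its total (s^-1).  Sojourns are returned
    in ms; the final sojourn is truncated at duration_ms.
    """
    np.random.seed(seed)
    n = exit_rates.shape[0]
    cap = 1024
    states = np.empty(cap, dtype=np.int64)
    sojourns = np.empty(cap)
    t = 0.0
    state = init_state
    k = 0
    while t < duration_ms:
        rate = exit_rates[state]
        if rate <= 0.0:
            dwell = duration_ms - t
        else:
            dwell = np.random.exponential(1.0 / rate) * 1000.0
        if t + dwell > duration_ms:
            dwell = duration_ms - t
        if k == cap:
            cap *= 2
            new_states = np.empty(cap, dtype=np.int64)
            new_soj = np.empty(cap)
            new_states[:k] = states
            new_soj[:k] = sojourns
            states = new_states
            sojourns = new_soj
        states[k] = state
        sojourns[k] = dwell
        k += 1
        t += dwell
        if t >= duration_ms:
            break
        u = np.random.random() * rate
        nxt = 0
        for j in range(n):
            if u <= q_off_cum[state, j]:
                nxt = j
                break
        state = nxt
    return states[:k], sojourns[:k]
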