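"""Numerical kernels for the HBD-class HMM, compiled with numba.

The transition kernel has the structure
``A[c, c'] = stay_c * [c == c'] + (1 - stay_c) * m_c'`` with
``stay_c = exp(-R_c * d)``, which lets the forward/backward recursions run in
O(S) per marker instead of O(S^2). Viterbi keeps the explicit O(S^2) maximum
so the first-index tie-break is exact.
"""

from __future__ import annotations

import numpy as np
from numba import njit

_FLOOR = 1e-300


@njit(cache=False)
def forward_backward_chrom(stay, B, m):
    """Scaled forward-backward over one chromosome.

    Parameters
    ----------
    stay : (T-1, S) segment-continuation probabilities exp(-R*d) per gap.
    B : (T, S) emission likelihoods (rows of ones where the genotype is missing).
    m : (S,) mixing proportions; also the chromosome-start distribution.

    Returns
    -------
    gamma : (T, S) posterior state probabilities.
    loglik : float
    reset_counts : (S,) expected number of within-chromosome segment starts
        landing in each state (reset events, including resets into the same
        state), for the EM M-step.
    """
    T, S = B.shape
    alpha = np.empty((T, S))
    scale = np.empty(T)

    a = m * B[0]
    c0 = a.sum()
    if c0 < _FLOOR:
        c0 = _FLOOR
    alpha[0] = a / c0
    scale[0] = c0
    for t in range(1, T):
        reset_mass = 0.0
        for s in range(S):
            reset_mass += alpha[t - 1, s] * (1.0 - stay[t - 1, s])
        ct = 0.0
        for s in range(S):
            v = (alpha[t - 1, s] * stay[t - 1, s] + reset_mass * m[s]) * B[t, s]
            alpha[t, s] = v
            ct += v
        if ct < _FLOOR:
            ct = _FLOOR
        for s in range(S):
            alpha[t, s] /= ct
        scale[t] = ct

    beta = np.empty((T, S))
    beta[T - 1] = 1.0
    reset_counts = np.zeros(S)
    for t in range(T - 2, -1, -1):
        common = 0.0
        for s in range(S):
            common += m[s] * B[t + 1, s] * beta[t + 1, s]
        # expected resets across the gap t -> t+1
        out_mass = 0.0
        for s in range(S):
            out_mass += alpha[t, s] * (1.0 - stay[t, s])
        for s in range(S):
            beta[t, s] = (stay[t, s] * B[t + 1, s] * beta[t + 1, s]
                          + (1.0 - stay[t, s]) * common) / scale[t + 1]
            reset_counts[s] += (out_mass * m[s] * B[t + 1, s]
                                * beta[t + 1, s] / scale[t + 1])

    gamma = alpha * beta
    for t in range(T):
        tot = gamma[t].sum()
        if tot > 0.0:
            gamma[t] /= tot

    loglik = 0.0
    for t in range(T):
        loglik += np.log(scale[t])
    return gamma, loglik, reset_counts


@njit(cache=False)
def viterbi_chrom(stay, B, m):
    """Log-space Viterbi over one chromosome; ties go to the lowest state index.

    Returns (path, best_log_prob).
    """
    T, S = B.shape
    logB = np.log(np.maximum(B, _FLOOR))
    delta = np.empty((T, S))
    back = np.zeros((T, S), dtype=np.int64)
    logm = np.log(np.maximum(m, _FLOOR))
    for s in range(S):
        delta[0, s] = logm[s] + logB[0, s]
    for t in range(1, T):
        for s2 in range(S):
            best = -np.inf
            arg = 0
            for s1 in range(S):
                a = stay[t - 1, s1] * (1.0 if s1 == s2 else 0.0) \
                    + (1.0 - stay[t - 1, s1]) * m[s2]
                v = delta[t - 1, s1] + np.log(max(a, _FLOOR))
                if v > best:  # strict: keeps the lowest s1 on ties
                    best = v
                    arg = s1
            delta[t, s2] = best + logB[t, s2]
            back[t, s2] = arg
    best = -np.inf
    last = 0
    for s in range(S):
        if delta[T - 1, s] > best:
            best = delta[T - 1, s]
            last = s
    path = np.empty(T, dtype=np.int64)
    path[T - 1] = last
    for t in range(T - 2, -1, -1):
        path[t] = back[t + 1, path[t + 1]]
    return path, best


@njit(cache=False)
def sample_state_path(pterm, m, u_term, u_reset):
    """Simulate one chromosome's latent state path at marker resolution.

    pterm : (S,) per-step segment-termination probability 1 - exp(-R*spacing).
    u_term, u_reset : (T,) uniform draws; u_reset[0] picks the initial state.

    Returns (states, new_segment) where new_segment[t] flags markers at which
    a fresh segment begins (including resets back into the same class).
    """
    T = u_term.shape[0]
    S = m.shape[0]
    cum = np.empty(S)
    acc = 0.0
    for s in range(S):
        acc += m[s]
        cum[s] = acc
    states = np.empty(T, dtype=np.int64)
    new_seg = np.zeros(T, dtype=np.bool_)

    def pick(u):
        for s in range(S):
            if u <= cum[s]:
                return s
        return S - 1

    st = pick(u_reset[0])
    states[0] = st
    new_seg[0] = True
    for t in range(1, T):
        if u_term[t] < pterm[st]:
            st = pick(u_reset[t])
            new_seg[t] = True
        states[t] = st
    return states, new_seg
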