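"""Numba kernels for the structured 4-state NHMM recursions.

The transition matrix at each step has a single stay probability f on the
diagonal and (1-f)/3 elsewhere, so the forward/backward/Viterbi updates are
O(S) per step instead of O(S^2).  Chains are per-gene and typically a few
thousand positions, decoded thousands of times during EM, which is why these
inner loops are compiled.
"""

import numpy as np
from numba import njit


@njit(cache=True)
def fb_structured(loge, f):
    """Scaled forward-backward for the stay/switch-structured NHMM.

    loge: (T, S) log emissions; f: (T-1,) stay probabilities (step i governs
    the transition from position i to i+1).  Returns (gamma, stay_post,
    loglik) where stay_post[i] is the posterior probability of remaining in
    the same state across step i.
    """
    T, S = loge.shape
    gamma = np.empty((T, S))
    stay_post = np.empty(T - 1)
    # emissions scaled per position for numerical stability
    m = np.empty(T)
    e = np.empty((T, S))
    for t in range(T):
        mt = loge[t, 0]
        for s in range(1, S):
            if loge[t, s] > mt:
                mt = loge[t, s]
        m[t] = mt
        for s in range(S):
            e[t, s] = np.exp(loge[t, s] - mt)

    alpha = np.empty((T, S))
    cnorm = np.empty(T)
    tot = 0.0
    for s in range(S):
        alpha[0, s] = e[0, s] / S
        tot += alpha[0, s]
    cnorm[0] = tot
    for s in range(S):
        alpha[0, s] /= tot
    for t in range(T - 1):
        ft = f[t]
        off = (1.0 - ft) / 3.0
        asum = 0.0
        for s in range(S):
            asum += alpha[t, s]
        tot = 0.0
        for s in range(S):
            v = e[t + 1, s] * (ft * alpha[t, s] + off * (asum - alpha[t, s]))
            alpha[t + 1, s] = v
            tot += v
        cnorm[t + 1] = tot
        for s in range(S):
            alpha[t + 1, s] /= tot

    beta = np.empty((T, S))
    for s in range(S):
        beta[T - 1, s] = 1.0
    for t in range(T - 2, -1, -1):
        ft = f[t]
        off = (1.0 - ft) / 3.0
        eb = np.empty(S)
        ebsum = 0.0
        for s in range(S):
            eb[s] = e[t + 1, s] * beta[t + 1, s]
            ebsum += eb[s]
        for s in range(S):
            beta[t, s] = (ft * eb[s] + off * (ebsum - eb[s])) / cnorm[t + 1]

    for t in range(T):
        tot = 0.0
        for s in range(S):
            gamma[t, s] = alpha[t, s] * beta[t, s]
            tot += gamma[t, s]
        for s in range(S):
            gamma[t, s] /= tot

    for t in range(T - 1):
        ft = f[t]
        stay = 0.0
        for s in range(S):
            stay += alpha[t, s] * ft * e[t + 1, s] * beta[t + 1, s]
        stay_post[t] = stay / cnorm[t + 1]

    loglik = 0.0
    for t in range(T):
        loglik += np.log(cnorm[t]) + m[t]
    return gamma, stay_post, loglik


@njit(cache=True)
def viterbi_structured(loge, f, peak_penalty):
    """Most likely state path; ties resolved toward the lowest state index.

    ``peak_penalty`` is added to the log emissions of state 0 (the peak
    state) before decoding, implementing the peak-core narrowing used for
    protocols with long peak tails.
    """
    T, S = loge.shape
    delta = np.empty((T, S))
    back = np.empty((T, S), dtype=np.int64)
    logpi = -np.log(S)
    for s in range(S):
        pen = peak_penalty if s == 0 else 0.0
        delta[0, s] = logpi + loge[0, s] + pen
    for t in range(1, T):
        lf = np.log(f[t - 1])
        lo = np.log((1.0 - f[t - 1]) / 3.0)
        for s in range(S):
            best = -np.inf
            arg = 0
            for sp in range(S):
                v = delta[t - 1, sp] + (lf if sp == s else lo)
                if v > best:
                    best = v
                    arg = sp
            pen = peak_penalty if s == 0 else 0.0
            delta[t, s] = best + loge[t, s] + pen
            back[t, s] = arg
    path = np.empty(T, dtype=np.int64)
    best = -np.inf
    arg = 0
    for s in range(S):
        if delta[T - 1, s] > best:
            best = delta[T - 1, s]
            arg = s
    path[T - 1] = arg
    for t in range(T - 2, -1, -1):
        path[t] = back[t + 1, path[t + 1]]
    return path, best
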