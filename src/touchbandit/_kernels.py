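"""Sequential inner loops (numba-compiled).

Trial-by-trial recursions — the RLCK likelihood, the HMM forward/backward
passes and Viterbi — cannot be vectorised over time, so they live here as
tight scalar loops. Choices are coded 0 = left, 1 = right; HMM states are
0 = explore, 1 = exploit-left, 2 = exploit-right throughout.
"""

from __future__ import annotations

import numpy as np
from numba import njit

_LOG_ZERO = -1e30


@njit(cache=True)
def _log1pexp(z):
    # log(1 + exp(z)), stable
    if z > 30.0:
        return z
    return np.log1p(np.exp(z))


@njit(cache=True)
def rlck_negloglik(alpha, beta, bias, kappa, choices, rewards):
    """Negative log-likelihood of one session under the RLCK policy.

    Values start at 0.5, choice-kernel traces at 0; the kernel learning
    rate is tied to alpha so the model has exactly four free parameters.
    """
    ql, qr = 0.5, 0.5
    cl, cr = 0.0, 0.0
    nll = 0.0
    for i in range(choices.shape[0]):
        z = beta * (ql - qr) + bias + kappa * (cl - cr)
        # log P(left) = -log(1+exp(-z)); log P(right) = -log(1+exp(z))
        if choices[i] == 0:
            nll += _log1pexp(-z)
        else:
            nll += _log1pexp(z)
        r = rewards[i]
        if choices[i] == 0:
            ql += alpha * (r - ql)
            cl += alpha * (1.0 - cl)
            cr += alpha * (0.0 - cr)
        else:
            qr += alpha * (r - qr)
            cr += alpha * (1.0 - cr)
            cl += alpha * (0.0 - cl)
    return nll


@njit(cache=True)
def rlck_simulate(alpha, beta, bias, kappa, p_left, p_right, u_choice, u_reward):
    """Simulate choices and rewards from an RLCK agent on a given walk."""
    n = p_left.shape[0]
    choices = np.empty(n, dtype=np.int64)
    rewards = np.empty(n, dtype=np.int64)
    ql, qr = 0.5, 0.5
    cl, cr = 0.0, 0.0
    for t in range(n):
        z = beta * (ql - qr) + bias + kappa * (cl - cr)
        p_l = 1.0 / (1.0 + np.exp(-z))
        c = 0 if u_choice[t] < p_l else 1
        p_rew = p_left[t] if c == 0 else p_right[t]
        r = 1 if u_reward[t] < p_rew else 0
        choices[t] = c
        rewards[t] = r
        if c == 0:
            ql += alpha * (r - ql)
            cl += alpha * (1.0 - cl)
            cr += alpha * (0.0 - cr)
        else:
            qr += alpha * (r - qr)
            cr += alpha * (1.0 - cr)
            cl += alpha * (0.0 - cl)
    return choices, rewards


@njit(cache=True)
def hmm_forward(choices, trans, emit_left, init):
    """Scaled forward pass. Returns (loglik, alpha_hat (T,3), scales (T,))."""
    T = choices.shape[0]
    a = np.empty((T, 3))
    c = np.empty(T)
    for s in range(3):
        e = emit_left[s] if choices[0] == 0 else 1.0 - emit_left[s]
        a[0, s] = init[s] * e
    c[0] = a[0].sum()
    a[0] /= c[0]
    for t in range(1, T):
        for s in range(3):
            acc = 0.0
            for u in range(3):
                acc += a[t - 1, u] * trans[u, s]
            e = emit_left[s] if choices[t] == 0 else 1.0 - emit_left[s]
            a[t, s] = acc * e
        c[t] = a[t].sum()
        a[t] /= c[t]
    return np.log(c).sum(), a, c


@njit(cache=True)
def hmm_forward_backward(choices, trans, emit_left, init):
    """Forward-backward. Returns (loglik, gamma (T,3), xi_sum (3,3))."""
    ll, a, c = hmm_forward(choices, trans, emit_left, init)
    T = choices.shape[0]
    b = np.empty((T, 3))
    b[T - 1] = 1.0
    for t in range(T - 2, -1, -1):
        for s in range(3):
            acc = 0.0
            for u in range(3):
                e = emit_left[u] if choices[t + 1] == 0 else 1.0 - emit_left[u]
                acc += trans[s, u] * e * b[t + 1, u]
            b[t, s] = acc / c[t + 1]
    gamma = a * b
    # renormalise against round-off
    for t in range(T):
        gamma[t] /= gamma[t].sum()
    xi = np.zeros((3, 3))
    for t in range(T - 1):
        denom = 0.0
        tmp = np.empty((3, 3))
        for s in range(3):
            for u in range(3):
                e = emit_left[u] if choices[t + 1] == 0 else 1.0 - emit_left[u]
                v = a[t, s] * trans[s, u] * e * b[t + 1, u] / c[t + 1]
                tmp[s, u] = v
                denom += v
        xi += tmp / denom
    return ll, gamma, xi


@njit(cache=True)
def hmm_viterbi(choices, trans, emit_left, init):
    """Most probable constrained state path (log-space Viterbi)."""
    T = choices.shape[0]
    logtrans = np.empty((3, 3))
    for s in range(3):
        for u in range(3):
            logtrans[s, u] = np.log(trans[s, u]) if trans[s, u] > 0 else _LOG_ZERO

    def _logemit(s, choice):
        e = emit_left[s] if choice == 0 else 1.0 - emit_left[s]
        return np.log(e) if e > 0 else _LOG_ZERO

    delta = np.empty((T, 3))
    back = np.zeros((T, 3), dtype=np.int64)
    for s in range(3):
        li = np.log(init[s]) if init[s] > 0 else _LOG_ZERO
        delta[0, s] = li + _logemit(s, choices[0])
    for t in range(1, T):
        for s in range(3):
            best, arg = -np.inf, 0
            for u in range(3):
                v = delta[t - 1, u] + logtrans[u, s]
                if v > best:
                    best, arg = v, u
            delta[t, s] = best + _logemit(s, choices[t])
            back[t, s] = arg
    path = np.empty(T, dtype=np.int64)
    path[T - 1] = np.argmax(delta[T - 1])
    for t in range(T - 2, -1, -1):
        path[t] = back[t + 1, path[t + 1]]
    return path
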