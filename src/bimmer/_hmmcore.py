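"""Scaled forward-backward and Viterbi kernels (numba, generic state count).

Emissions are supplied as log-probabilities and rescaled per bin before the
linear-space recursions, so chains of hundreds of thousands of bins neither
underflow nor overflow.  The total data log-likelihood is recovered as the
sum of the per-bin log normalizers plus the emission shifts.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["forward_backward", "viterbi", "scaled_emissions"]


def scaled_emissions(logem: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Shift log emissions per bin and exponentiate: e_i = exp(logem_i - s_i)."""
    shift = logem.max(axis=1)
    if not np.all(np.isfinite(shift)):
        raise FloatingPointError("a bin has -inf emission for every state")
    return np.exp(logem - shift[:, None]), shift


@njit(cache=True)
def _forward(pi, T, em, alpha_hat, c):  # pragma: no cover - numba
    M, S = em.shape
    tot = 0.0
    for s in range(S):
        alpha_hat[0, s] = pi[s] * em[0, s]
    c0 = 0.0
    for s in range(S):
        c0 += alpha_hat[0, s]
    c[0] = c0
    for s in range(S):
        alpha_hat[0, s] /= c0
    for i in range(1, M):
        ci = 0.0
        for s in range(S):
            a = 0.0
            for sp in range(S):
                a += alpha_hat[i - 1, sp] * T[sp, s]
            a *= em[i, s]
            alpha_hat[i, s] = a
            ci += a
        c[i] = ci
        for s in range(S):
            alpha_hat[i, s] /= ci
    for i in range(M):
        tot += np.log(c[i])
    return tot


@njit(cache=True)
def _backward(T, em, c, beta_hat, alpha_hat, gamma, xi_sum):  # pragma: no cover
    M, S = em.shape
    for s in range(S):
        beta_hat[M - 1, s] = 1.0
        gamma[M - 1, s] = alpha_hat[M - 1, s]
    for i in range(M - 2, -1, -1):
        for s in range(S):
            b = 0.0
            for sn in range(S):
                b += T[s, sn] * em[i + 1, sn] * beta_hat[i + 1, sn]
            beta_hat[i, s] = b / c[i + 1]
        gs = 0.0
        for s in range(S):
            g = alpha_hat[i, s] * beta_hat[i, s]
            gamma[i, s] = g
            gs += g
        for s in range(S):
            gamma[i, s] /= gs
        # pairwise posterior mass at step i -> i+1, accumulated over bins
        for sp in range(S):
            ap = alpha_hat[i, sp]
            for s in range(S):
                xi_sum[sp, s] += (
                    ap * T[sp, s] * em[i + 1, s] * beta_hat[i + 1, s] / c[i + 1]
                )


def forward_backward(pi, T, logem):
    """Run the scaled recursions.

    Returns ``(loglik, gamma, alpha_hat, beta_hat, c, xi_sum)`` where
    ``gamma`` is the (M, S) posterior, ``xi_sum`` the (S, S) pairwise
    posterior mass summed over all adjacent bin pairs, and ``c`` the per-bin
    normalizers of the *scaled* emissions.
    """
    em, shift = scaled_emissions(logem)
    M, S = em.shape
    alpha_hat = np.empty((M, S))
    beta_hat = np.empty((M, S))
    gamma = np.empty((M, S))
    xi_sum = np.zeros((S, S))
    c = np.empty(M)
    loglik = _forward(np.ascontiguousarray(pi, dtype=np.float64),
                      np.ascontiguousarray(T, dtype=np.float64), em, alpha_hat, c)
    _backward(np.ascontiguousarray(T, dtype=np.float64), em, c, beta_hat,
              alpha_hat, gamma, xi_sum)
    return loglik + shift.sum(), gamma, alpha_hat, beta_hat, c, xi_sum


@njit(cache=True)
def _viterbi(log_pi, log_T, logem):  # pragma: no cover - numba
    M, S = logem.shape
    delta = np.empty((M, S))
    back = np.zeros((M, S), dtype=np.int64)
    for s in range(S):
        delta[0, s] = log_pi[s] + logem[0, s]
    for i in range(1, M):
        for s in range(S):
            best = -np.inf
            arg = 0
            for sp in range(S):
                v = delta[i - 1, sp] + log_T[sp, s]
                if v > best:  # strict: ties resolve to the lower prev index
                    best = v
                    arg = sp
            delta[i, s] = best + logem[i, s]
            back[i, s] = arg
    path = np.empty(M, dtype=np.int64)
    best = -np.inf
    arg = 0
    for s in range(S):
        if delta[M - 1, s] > best:
            best = delta[M - 1, s]
            arg = s
    path[M - 1] = arg
    for i in range(M - 2, -1, -1):
        path[i] = back[i + 1, path[i + 1]]
    return path


def viterbi(pi, T, logem, floor: float = 1e-300):
    """Most probable state path; ties break to the lower state index."""
    with np.errstate(divide="ignore"):
        log_pi = np.log(np.maximum(np.asarray(pi, dtype=np.float64), floor))
        log_T = np.log(np.maximum(np.asarray(T, dtype=np.float64), floor))
    return _viterbi(log_pi, log_T, np.ascontiguousarray(logem, dtype=np.float64))
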