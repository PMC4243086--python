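"""Generative model of the coupled three-chain HMM.

The joint hidden state at bin ``i`` is the triple ``(dm, mc, mn)``; the model
factorizes bin-to-bin as

    P(dm_i | dm_{i-1}) * P(mc_i | mc_{i-1}) * P(mn_i | mn_{i-1}, mc_i, dm_i)

with the last factor the alpha-weighted mixture of the normal chain's own
transition and the coupling indicator ``1{mn = mc XOR dm}``.  The eight joint
states are indexed ``4*dm + 2*mc + mn`` (dm major) throughout the package.

This module holds the exact scalar/small-matrix primitives; the scaled
dynamic-programming recursions live in :mod:`bimmer.em`.
"""

from __future__ import annotations

import numpy as np

from .params import PROB_FLOOR, FirstLayerParams, ModelParams

__all__ = [
    "N_JOINT_STATES",
    "STATE_TRIPLES",
    "state_index",
    "state_triple",
    "coupling_probability",
    "mixture_emission",
    "joint_transition_tensor",
    "joint_initial_distribution",
    "categorize_counts",
    "category_histogram",
    "emission_logpmf_bin",
    "cohort_emission_loglik",
    "joint_emission_loglik",
    "complete_data_loglik",
]

N_JOINT_STATES = 8

#: Fixed joint-state ordering: index = 4*dm + 2*mc + mn.
STATE_TRIPLES: tuple[tuple[int, int, int], ...] = tuple(
    (dm, mc, mn) for dm in (0, 1) for mc in (0, 1) for mn in (0, 1)
)


def state_index(dm: int, mc: int, mn: int) -> int:
    """Map a (dm, mc, mn) triple to its joint-state index."""
    _check_binary(dm, mc, mn)
    return 4 * dm + 2 * mc + mn


def state_triple(index: int) -> tuple[int, int, int]:
    """Inverse of :func:`state_index`."""
    if not 0 <= index < N_JOINT_STATES:
        raise ValueError(f"joint state index must be in 0..7, got {index}")
    return (index >> 2) & 1, (index >> 1) & 1, index & 1


def _check_binary(*vals: int) -> None:
    for v in vals:
        if v not in (0, 1):
            raise ValueError(f"state variables must be 0 or 1, got {v!r}")


def coupling_probability(mn: int, mc: int, dm: int, eps: float = 0.0) -> float:
    """P(mn | mc, dm) under the coupling rule: dm=1 forces mn != mc.

    Returns ``1 - eps`` when ``mn == mc XOR dm`` and ``eps`` otherwise.  The
    model proper uses the hard indicator (``eps = 0``); a small ``eps``
    softens it for experimentation.
    """
    _check_binary(mn, mc, dm)
    return 1.0 - eps if mn == (mc ^ dm) else eps


def mixture_emission(
    mn: int,
    mn_prev: int,
    mc: int,
    dm: int,
    A_n: np.ndarray,
    alpha: float,
    eps: float = 0.0,
) -> float:
    """The fused transition P(mn | mn_prev, mc, dm).

    A convex combination ``alpha * A_n[mn_prev, mn] +
    (1 - alpha) * P(mn | mc, dm)``; sums to 1 over ``mn``.
    """
    _check_binary(mn, mn_prev, mc, dm)
    A_n = np.asarray(A_n, dtype=float)
    return alpha * A_n[mn_prev, mn] + (1.0 - alpha) * coupling_probability(mn, mc, dm, eps)


def joint_transition_tensor(params: ModelParams) -> np.ndarray:
    """8x8 joint transition matrix over (dm, mc, mn) triples.

    Entry ``[s_prev, s] = A_dm[dm', dm] * A_c[mc', mc] *
    mixture(mn | mn', mc, dm)``; every row sums to 1.
    """
    sec = params.second
    A_dm, A_c, A_n = sec.A_dm, params.cancer.A, params.normal.A
    alpha, eps = sec.alpha, params.coupling_eps
    T = np.empty((N_JOINT_STATES, N_JOINT_STATES))
    for sp, (dmp, mcp, mnp) in enumerate(STATE_TRIPLES):
        for s, (dm, mc, mn) in enumerate(STATE_TRIPLES):
            T[sp, s] = (
                A_dm[dmp, dm]
                * A_c[mcp, mc]
                * mixture_emission(mn, mnp, mc, dm, A_n, alpha, eps)
            )
    return T


def joint_initial_distribution(params: ModelParams) -> np.ndarray:
    """Initial distribution over the 8 joint states at bin 1.

    The first-bin mixture uses the normal chain's initial pmf in place of its
    transition row: ``P(mn_1 | mc_1, dm_1) = alpha * pi_n[mn_1] +
    (1 - alpha) * coupling(mn_1 | mc_1, dm_1)``.
    """
    sec = params.second
    pi_dm = sec.initial_dist
    pi_c = params.cancer.initial_dist
    pi_n = params.normal.initial_dist
    alpha, eps = sec.alpha, params.coupling_eps
    pi = np.empty(N_JOINT_STATES)
    for s, (dm, mc, mn) in enumerate(STATE_TRIPLES):
        mix = alpha * pi_n[mn] + (1.0 - alpha) * coupling_probability(mn, mc, dm, eps)
        pi[s] = pi_dm[dm] * pi_c[mc] * mix
    return pi


def categorize_counts(counts: np.ndarray, K: int) -> np.ndarray:
    """Map raw read counts into emission categories 0..K (cap at K)."""
    counts = np.asarray(counts)
    if np.any(counts < 0):
        raise ValueError("read counts must be non-negative")
    return np.minimum(counts, K).astype(np.int64)


def category_histogram(counts: np.ndarray, K: int) -> np.ndarray:
    """Per-bin category occupancy: (M, K+1) matrix of sample tallies.

    ``H[i, k]`` is the number of samples whose (capped) count at bin ``i``
    equals ``k``; the i.i.d.-replicate emission log-likelihood of a bin is
    then the inner product of ``H[i]`` with the log pmf row.
    """
    cat = categorize_counts(counts, K)
    if cat.ndim == 1:
        cat = cat[:, None]
    M = cat.shape[0]
    H = np.zeros((M, K + 1), dtype=np.int64)
    for k in range(K + 1):
        H[:, k] = (cat == k).sum(axis=1)
    return H


def cohort_emission_loglik(
    counts: np.ndarray, B: np.ndarray, floor: float | None = PROB_FLOOR
) -> np.ndarray:
    """(M, 2) log P(X_i | state) for one cohort, product over samples.

    With ``floor=None`` zero-probability categories yield -inf.
    """
    B = np.asarray(B, dtype=float)
    K = B.shape[1] - 1
    H = category_histogram(counts, K)
    if floor is not None:
        return H @ np.log(np.maximum(B, floor)).T
    # unfloored: an observed zero-probability category yields exactly -inf
    # (0 * -inf must not poison unobserved categories)
    logB = np.where(B > 0, np.log(np.maximum(B, 1e-300)), 0.0)
    out = H @ logB.T
    impossible = (H > 0) @ (B.T == 0)
    out[impossible] = -np.inf
    return out


def emission_logpmf_bin(
    counts_n: np.ndarray, counts_c: np.ndarray, Bn: np.ndarray, Bc: np.ndarray
) -> np.ndarray:
    """Log emission of a single bin for all four (mn, mc) combinations.

    Returns a (2, 2) array indexed ``[mn, mc]``:
    ``sum_j log Bn[mn, cat(xn_j)] + sum_k log Bc[mc, cat(xc_k)]``.
    Zero-probability categories give -inf (no flooring here; EM callers
    floor the pmfs instead).
    """
    ln = cohort_emission_loglik(np.atleast_1d(counts_n)[None, :], Bn, floor=None)[0]
    lc = cohort_emission_loglik(np.atleast_1d(counts_c)[None, :], Bc, floor=None)[0]
    return ln[:, None] + lc[None, :]


def joint_emission_loglik(
    counts_n: np.ndarray,
    counts_c: np.ndarray,
    normal: FirstLayerParams,
    cancer: FirstLayerParams,
    floor: float | None = PROB_FLOOR,
) -> np.ndarray:
    """(M, 8) log emission over joint states (dm carries no emission)."""
    ln = cohort_emission_loglik(counts_n, normal.B, floor)
    lc = cohort_emission_loglik(counts_c, cancer.B, floor)
    M = ln.shape[0]
    if lc.shape[0] != M:
        raise ValueError("normal and cancer tracks must cover the same bins")
    logem = np.empty((M, N_JOINT_STATES))
    for s, (dm, mc, mn) in enumerate(STATE_TRIPLES):
        logem[:, s] = ln[:, mn] + lc[:, mc]
    return logem


def complete_data_loglik(
    params: ModelParams,
    dm: np.ndarray,
    mc: np.ndarray,
    mn: np.ndarray,
    counts_n: np.ndarray,
    counts_c: np.ndarray,
) -> float:
    """Log of the complete-data likelihood P(Xn, Xc, mc, mn, dm | Psi).

    Sums the initial, transition and emission log factors exactly as the
    model factorizes; -inf if the configuration has zero probability.
    """
    dm = np.asarray(dm, int)
    mc = np.asarray(mc, int)
    mn = np.asarray(mn, int)
    M = len(dm)
    if not (len(mc) == len(mn) == M):
        raise ValueError("state chains must have equal length")
    counts_n = np.atleast_2d(np.asarray(counts_n))
    counts_c = np.atleast_2d(np.asarray(counts_c))
    if counts_n.shape[0] != M or counts_c.shape[0] != M:
        raise ValueError("count matrices must have one row per bin")

    pi = joint_initial_distribution(params)
    T = joint_transition_tensor(params)
    states = 4 * dm + 2 * mc + mn
    with np.errstate(divide="ignore"):
        total = float(np.log(pi[states[0]]))
        for i in range(1, M):
            total += float(np.log(T[states[i - 1], states[i]]))
    logem = joint_emission_loglik(
        counts_n, counts_c, params.normal, params.cancer, floor=None
    )
    total += float(logem[np.arange(M), states].sum())
    return total
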