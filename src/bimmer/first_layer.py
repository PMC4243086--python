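"""Per-cohort 2-state methylation HMM trained by Baum-Welch.

Each cohort (normal, cancer) is fit independently before the second-layer EM:
a binary methylated/unmethylated chain with a categorical emission over count
categories 0..K, replicate samples treated as i.i.d. draws within a bin (the
bin emission is the product over samples).  The fitted parameters are then
frozen during the differential-chain EM.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from . import _hmmcore
from .model import category_histogram, cohort_emission_loglik
from .params import PROB_FLOOR, FirstLayerParams

__all__ = ["BaumWelchResult", "baum_welch", "first_layer_viterbi", "default_init"]


@dataclass
class BaumWelchResult:
    """Outcome of a Baum-Welch fit.

    ``loglik_trace`` holds the data log-likelihood evaluated under the
    parameters *entering* each iteration; EM guarantees it never decreases.
    """

    params: FirstLayerParams
    loglik_trace: np.ndarray
    n_iter: int
    converged: bool
    degenerate: bool = field(default=False)


def _as_matrix(counts) -> np.ndarray:
    counts = getattr(counts, "counts", counts)
    counts = np.asarray(counts)
    if counts.ndim == 1:
        counts = counts[:, None]
    return counts


def default_init(counts: np.ndarray, K: int) -> FirstLayerParams:
    """Data-driven starting point.

    Transitions start sticky ([[0.9, 0.1], [0.1, 0.9]]) and tau at 0.5;
    emission rows are seeded from a median split of per-bin mean counts
    (bins above the median seed state 1), so the two states separate even
    when the global category mix is far from uniform.
    """
    counts = _as_matrix(counts)
    H = category_histogram(counts, K)
    mean = counts.mean(axis=1)
    hi = mean > np.median(mean)
    if hi.sum() == 0 or (~hi).sum() == 0:  # constant data; uniform-ish seed
        base = H.sum(axis=0).astype(float) + 1.0
        B = np.vstack([base, base[::-1]])
    else:
        B = np.vstack([H[~hi].sum(axis=0), H[hi].sum(axis=0)]).astype(float)
        B += 1.0  # pseudocount keeps every category reachable
    B /= B.sum(axis=1, keepdims=True)
    return FirstLayerParams(tau=0.5, A=np.array([[0.9, 0.1], [0.1, 0.9]]), B=B)


def canonicalize(params: FirstLayerParams) -> FirstLayerParams:
    """Resolve label switching: state 1 is the higher-emission-mean state."""
    k = np.arange(params.K + 1)
    means = params.B @ k
    if means[0] <= means[1]:
        return params
    perm = [1, 0]
    return FirstLayerParams(
        tau=1.0 - params.tau, A=params.A[np.ix_(perm, perm)], B=params.B[perm]
    )


def baum_welch(
    counts,
    K: int = 5,
    init: FirstLayerParams | None = None,
    max_iter: int = 100,
    tol: float = 1e-4,
    freeze_tau: bool = False,
) -> BaumWelchResult:
    """Fit the 2-state categorical HMM by EM (Baum-Welch).

    Parameters
    ----------
    counts : BinnedCounts or (M, N) array
        Raw per-bin read counts for one cohort; categorized to 0..K.
    K : int
        Largest emission category; counts above K are capped.
    init : FirstLayerParams, optional
        Starting point; defaults to :func:`default_init`.
    max_iter, tol
        Stop when the absolute log-likelihood change drops below ``tol``.
    freeze_tau : bool
        Keep the initial-state probability fixed at its starting value
        (useful when it is pinned near-degenerate a priori).

    Returns
    -------
    BaumWelchResult
        With states canonicalized so state 1 has the higher emission mean.
    """
    counts = _as_matrix(counts)
    M, N = counts.shape
    H = category_histogram(counts, K)
    degenerate = bool(np.all(counts == counts.flat[0]))
    if degenerate:
        warnings.warn(
            "all counts identical: single effective state, parameters "
            "unidentifiable",
            RuntimeWarning,
            stacklevel=2,
        )
    params = init if init is not None else default_init(counts, K)
    if params.K != K:
        raise ValueError("init emission width inconsistent with K")

    trace = []
    converged = False
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        logB = np.log(np.maximum(params.B, PROB_FLOOR))
        logem = H @ logB.T
        loglik, gamma, _, _, _, xi_sum = _hmmcore.forward_backward(
            params.initial_dist, params.A, logem
        )
        trace.append(loglik)
        if len(trace) > 1 and abs(trace[-1] - trace[-2]) < tol:
            converged = True
            break
        # M-step; a state never visited keeps its previous transition row
        A = params.A.copy()
        row_mass = xi_sum.sum(axis=1)
        for d in (0, 1):
            if row_mass[d] > 1e-12:
                A[d] = xi_sum[d] / row_mass[d]
        B = gamma.T @ H
        B = np.maximum(B, PROB_FLOOR)
        B /= B.sum(axis=1, keepdims=True)
        tau = params.tau if freeze_tau else float(gamma[0, 1])
        params = FirstLayerParams(tau=tau, A=A, B=B)
    return BaumWelchResult(
        params=canonicalize(params),
        loglik_trace=np.asarray(trace),
        n_iter=n_iter,
        converged=converged,
        degenerate=degenerate,
    )


def first_layer_viterbi(counts, params: FirstLayerParams) -> np.ndarray:
    """MAP methylation path for one cohort under its 2-state HMM."""
    counts = _as_matrix(counts)
    logem = cohort_emission_loglik(counts, params.B)
    return _hmmcore.viterbi(params.initial_dist, params.A, logem)
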