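"""EM inference for the differential-methylation chain.

With the two cohort HMMs trained and frozen, the remaining parameters are
Psi = {tau_dm, A_dm, alpha}: the differential chain's initial probability and
transitions, and the mixture weight that blends the normal chain's own
dynamics against the coupling indicator.  The E-step runs a scaled
forward-backward pass over the 8 joint (dm, mc, mn) states; the M-step
updates tau_dm and A_dm by expected-count ratios and alpha by safeguarded
Newton-Raphson on the (concave) expected complete-data log-likelihood.
Decoding is Viterbi over the joint chain; the soft score per bin is the
posterior P(dm_i = 1 | X).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize_scalar

from . import _hmmcore
from .model import (
    N_JOINT_STATES,
    STATE_TRIPLES,
    coupling_probability,
    joint_emission_loglik,
    joint_initial_distribution,
    joint_transition_tensor,
)
from .params import FirstLayerParams, ModelParams, SecondLayerParams

__all__ = [
    "JointPosterior",
    "EMState",
    "forward_backward",
    "m_step_tau_adm",
    "m_step_alpha",
    "fit",
    "viterbi_joint",
    "dm_posterior_score",
    "default_second_layer_init",
]

_ALPHA_LO, _ALPHA_HI = 1e-6, 1.0 - 1e-6


@dataclass
class JointPosterior:
    """Exact posterior over the 8-state joint chain.

    ``gamma[i, s]`` is P(state_i = s | X); ``xi_sum`` aggregates the pairwise
    posteriors over all adjacent bin pairs (sufficient for every M-step
    update); individual slices are available via :meth:`pairwise`.
    """

    gamma: np.ndarray
    loglik: float
    xi_sum: np.ndarray
    _alpha_hat: np.ndarray = field(repr=False)
    _beta_hat: np.ndarray = field(repr=False)
    _em: np.ndarray = field(repr=False)
    _c: np.ndarray = field(repr=False)
    _T: np.ndarray = field(repr=False)

    @property
    def n_bins(self) -> int:
        return self.gamma.shape[0]

    def pairwise(self, i: int) -> np.ndarray:
        """8x8 posterior P(state_{i-1}, state_i | X) for 1 <= i < M."""
        if not 1 <= i < self.n_bins:
            raise IndexError("pairwise posteriors exist for 1 <= i < M")
        xi = (
            self._alpha_hat[i - 1][:, None]
            * self._T
            * (self._em[i] * self._beta_hat[i])[None, :]
            / self._c[i]
        )
        return xi


@dataclass
class EMState:
    """Trace of one EM run over Psi = {tau_dm, A_dm, alpha}."""

    second: SecondLayerParams
    params: ModelParams
    loglik_trace: np.ndarray
    alpha_trace: np.ndarray
    n_iter: int
    converged: bool


def default_second_layer_init() -> SecondLayerParams:
    """Sticky-transition start: A_dm = [[0.9, 0.1], [0.1, 0.9]],
    tau_dm = 1e-5, alpha = 0.01."""
    return SecondLayerParams(
        tau_dm=1e-5, A_dm=np.array([[0.9, 0.1], [0.1, 0.9]]), alpha=0.01
    )


def _fb_from_logem(logem: np.ndarray, params: ModelParams) -> JointPosterior:
    pi = joint_initial_distribution(params)
    T = joint_transition_tensor(params)
    em, shift = _hmmcore.scaled_emissions(logem)
    loglik, gamma, a_hat, b_hat, c, xi_sum = _hmmcore.forward_backward(pi, T, logem)
    return JointPosterior(
        gamma=gamma,
        loglik=loglik,
        xi_sum=xi_sum,
        _alpha_hat=a_hat,
        _beta_hat=b_hat,
        _em=em,
        _c=c,
        _T=T,
    )


def forward_backward(counts_n, counts_c, params: ModelParams) -> JointPosterior:
    """E-step: exact joint-chain posteriors and data log-likelihood."""
    counts_n = np.atleast_2d(getattr(counts_n, "counts", counts_n))
    counts_c = np.atleast_2d(getattr(counts_c, "counts", counts_c))
    if counts_n.shape[0] == 0:
        raise ValueError("empty count track")
    logem = joint_emission_loglik(counts_n, counts_c, params.normal, params.cancer)
    return _fb_from_logem(logem, params)


def m_step_tau_adm(
    posterior: JointPosterior, prev: SecondLayerParams | None = None
) -> tuple[float, np.ndarray]:
    """Expected-count updates for the differential chain.

    tau_dm is the posterior probability that bin 1 is differential; each
    A_dm row is the expected dm transition mass out of that state,
    normalized.  A dm state with no posterior mass keeps its previous row.
    """
    gamma1 = posterior.gamma[0]
    tau_dm = float(gamma1[4:].sum())
    # collapse the 8x8 pairwise mass onto the dm margin
    dm_of = np.array([t[0] for t in STATE_TRIPLES])
    xi_dm = np.zeros((2, 2))
    for a in (0, 1):
        for b in (0, 1):
            xi_dm[a, b] = posterior.xi_sum[np.ix_(dm_of == a, dm_of == b)].sum()
    A_dm = np.array([[0.5, 0.5], [0.5, 0.5]]) if prev is None else prev.A_dm.copy()
    for a in (0, 1):
        denom = xi_dm[a].sum()
        if denom > 1e-12:
            A_dm[a] = xi_dm[a] / denom
        else:
            warnings.warn(
                f"dm state {a} carries no posterior mass; keeping its "
                "transition row",
                RuntimeWarning,
                stacklevel=2,
            )
    return tau_dm, A_dm


def _alpha_objective_terms(
    posterior: JointPosterior, params: ModelParams
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Weights w and mixture legs (a, b) of Q(alpha) = sum w log(a*alpha +
    b*(1-alpha)).

    Transition terms group by (mn_prev, mn, coupling value) and are read off
    the aggregated pairwise mass; the bin-1 term uses the normal chain's
    initial pmf in place of its transition row.
    """
    eps = params.coupling_eps
    A_n = params.normal.A
    pi_n = params.normal.initial_dist
    w, a, b = [], [], []
    for sp, (_, _, mnp) in enumerate(STATE_TRIPLES):
        for s, (dm, mc, mn) in enumerate(STATE_TRIPLES):
            w.append(posterior.xi_sum[sp, s])
            a.append(A_n[mnp, mn])
            b.append(coupling_probability(mn, mc, dm, eps))
    for s, (dm, mc, mn) in enumerate(STATE_TRIPLES):
        w.append(posterior.gamma[0, s])
        a.append(pi_n[mn])
        b.append(coupling_probability(mn, mc, dm, eps))
    w, a, b = np.asarray(w), np.asarray(a), np.asarray(b)
    keep = w > 0
    return w[keep], a[keep], b[keep]


def m_step_alpha(
    posterior: JointPosterior,
    params: ModelParams,
    tol: float = 1e-10,
    max_newton: int = 100,
) -> float:
    """Maximize Q over the mixture weight alpha in [0, 1].

    Q is concave in alpha (its second derivative is a negative weighted sum
    of squares), so Newton-Raphson from the current estimate converges
    quadratically; if a step ever leaves [0, 1] or the curvature degenerates,
    a bounded golden-section search takes over.  Flat objectives (every
    mixture leg pair equal) return the current alpha unchanged.
    """
    w, a, b = _alpha_objective_terms(posterior, params)
    d = a - b
    if np.all(np.abs(d) < 1e-15):
        return float(params.second.alpha)

    def grad_hess(x: float) -> tuple[float, float]:
        denom = x * a + (1.0 - x) * b
        g = float(np.sum(w * d / denom))
        h = float(-np.sum(w * (d / denom) ** 2))
        return g, h

    x = float(np.clip(params.second.alpha, _ALPHA_LO, _ALPHA_HI))
    ok = True
    for _ in range(max_newton):
        g, h = grad_hess(x)
        if abs(g) < tol * max(1.0, abs(h)):
            break
        if h >= -1e-300 or not np.isfinite(g):
            ok = False
            break
        step = -g / h
        x_new = x + step
        if not _ALPHA_LO <= x_new <= _ALPHA_HI:
            # the concave objective's maximizer may genuinely sit at a
            # boundary; probe the clipped point, else fall back
            x_new = float(np.clip(x_new, _ALPHA_LO, _ALPHA_HI))
            g_new, _ = grad_hess(x_new)
            if (x_new == _ALPHA_LO and g_new <= 0) or (
                x_new == _ALPHA_HI and g_new >= 0
            ):
                return x_new
            if x_new == x:
                ok = False
                break
        if abs(x_new - x) < tol:
            x = x_new
            break
        x = x_new
    else:
        ok = False
    if ok:
        return x

    def neg_q(x: float) -> float:
        return -float(np.sum(w * np.log(x * a + (1.0 - x) * b)))

    res = minimize_scalar(
        neg_q, bounds=(_ALPHA_LO, _ALPHA_HI), method="bounded",
        options={"xatol": 1e-10},
    )
    return float(res.x)


def fit(
    counts_n,
    counts_c,
    normal: FirstLayerParams,
    cancer: FirstLayerParams,
    init: SecondLayerParams | None = None,
    max_iter: int = 100,
    tol: float = 1e-4,
    coupling_eps: float = 0.0,
) -> EMState:
    """Run the second-layer EM with the cohort HMMs frozen.

    Iterates E-step (joint forward-backward) and M-step (tau_dm, A_dm,
    alpha) until the absolute data log-likelihood change drops below
    ``tol`` or ``max_iter`` is reached.  The returned trace is evaluated
    under the parameters entering each iteration and is non-decreasing.
    """
    counts_n = np.atleast_2d(getattr(counts_n, "counts", counts_n))
    counts_c = np.atleast_2d(getattr(counts_c, "counts", counts_c))
    second = init if init is not None else default_second_layer_init()
    logem = joint_emission_loglik(counts_n, counts_c, normal, cancer)

    trace: list[float] = []
    alphas: list[float] = []
    converged = False
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        params = ModelParams(
            normal=normal, cancer=cancer, second=second, coupling_eps=coupling_eps
        )
        posterior = _fb_from_logem(logem, params)
        if not np.isfinite(posterior.loglik):
            raise FloatingPointError(
                f"non-finite data log-likelihood at EM iteration {n_iter} "
                f"(alpha={second.alpha:.6g})"
            )
        trace.append(posterior.loglik)
        alphas.append(second.alpha)
        if len(trace) > 1 and abs(trace[-1] - trace[-2]) < tol:
            converged = True
            break
        tau_dm, A_dm = m_step_tau_adm(posterior, prev=second)
        alpha = m_step_alpha(posterior, params)
        second = SecondLayerParams(tau_dm=tau_dm, A_dm=A_dm, alpha=alpha)
    final = ModelParams(
        normal=normal, cancer=cancer, second=second, coupling_eps=coupling_eps
    )
    return EMState(
        second=second,
        params=final,
        loglik_trace=np.asarray(trace),
        alpha_trace=np.asarray(alphas),
        n_iter=n_iter,
        converged=converged,
    )


def viterbi_joint(
    counts_n, counts_c, params: ModelParams
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """MAP path over the joint chain, split into (dm, mc, mn) chains.

    Ties break deterministically toward the lower joint-state index.
    """
    counts_n = np.atleast_2d(getattr(counts_n, "counts", counts_n))
    counts_c = np.atleast_2d(getattr(counts_c, "counts", counts_c))
    logem = joint_emission_loglik(counts_n, counts_c, params.normal, params.cancer)
    pi = joint_initial_distribution(params)
    T = joint_transition_tensor(params)
    path = _hmmcore.viterbi(pi, T, logem)
    return (path >> 2) & 1, (path >> 1) & 1, path & 1


def dm_posterior_score(posterior: JointPosterior) -> np.ndarray:
    """Per-bin P(dm_i = 1 | X): the posterior mass on the four dm=1 states."""
    return posterior.gamma[:, 4:].sum(axis=1)
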