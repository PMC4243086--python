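"""Independent brute-force oracles used by the test suite.

Everything here is written from the model definition directly — scalar
probability products and exhaustive sums over all 8^M joint paths — and
deliberately avoids the package's dynamic-programming code paths, so it can
serve as ground truth for the forward-backward and Viterbi implementations.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy.special import logsumexp

TRIPLES = [(dm, mc, mn) for dm in (0, 1) for mc in (0, 1) for mn in (0, 1)]


def coupling(mn, mc, dm, eps=0.0):
    return 1.0 - eps if mn == (mc ^ dm) else eps


def oracle_transition(params):
    """8x8 joint transition built from scalar products (no package calls)."""
    A_dm, A_c, A_n = params.second.A_dm, params.cancer.A, params.normal.A
    a, e = params.second.alpha, params.coupling_eps
    T = np.empty((8, 8))
    for i, (dmp, mcp, mnp) in enumerate(TRIPLES):
        for j, (dm, mc, mn) in enumerate(TRIPLES):
            mix = a * A_n[mnp, mn] + (1 - a) * coupling(mn, mc, dm, e)
            T[i, j] = A_dm[dmp, dm] * A_c[mcp, mc] * mix
    return T


def oracle_initial(params):
    a, e = params.second.alpha, params.coupling_eps
    pi_dm = [1 - params.second.tau_dm, params.second.tau_dm]
    pi_c = [1 - params.cancer.tau, params.cancer.tau]
    pi_n = [1 - params.normal.tau, params.normal.tau]
    pi = np.empty(8)
    for j, (dm, mc, mn) in enumerate(TRIPLES):
        mix = a * pi_n[mn] + (1 - a) * coupling(mn, mc, dm, e)
        pi[j] = pi_dm[dm] * pi_c[mc] * mix
    return pi


def oracle_emission(counts_n, counts_c, params, floor=1e-10):
    """(M, 8) log emission by per-sample pmf lookups."""
    Bn = np.maximum(params.normal.B, floor)
    Bc = np.maximum(params.cancer.B, floor)
    K = Bn.shape[1] - 1
    M = counts_n.shape[0]
    logem = np.zeros((M, 8))
    for i in range(M):
        for j, (dm, mc, mn) in enumerate(TRIPLES):
            for x in counts_n[i]:
                logem[i, j] += np.log(Bn[mn, min(int(x), K)])
            for x in counts_c[i]:
                logem[i, j] += np.log(Bc[mc, min(int(x), K)])
    return logem


def enumerate_paths(counts_n, counts_c, params, floor=1e-10):
    """All-path log joint probabilities log P(X, path) for M <= ~7.

    Returns (paths, logp) where paths is (8^M, M) int and logp the matching
    vector of complete-data log likelihoods.
    """
    M = counts_n.shape[0]
    pi = oracle_initial(params)
    T = oracle_transition(params)
    logem = oracle_emission(counts_n, counts_c, params, floor)
    with np.errstate(divide="ignore"):
        lpi, lT = np.log(pi), np.log(T)
    paths = np.array(list(itertools.product(range(8), repeat=M)), dtype=np.int64)
    logp = lpi[paths[:, 0]] + logem[0][paths[:, 0]]
    for i in range(1, M):
        logp = logp + lT[paths[:, i - 1], paths[:, i]] + logem[i][paths[:, i]]
    return paths, logp


def oracle_loglik(counts_n, counts_c, params, floor=1e-10):
    _, logp = enumerate_paths(counts_n, counts_c, params, floor)
    return logsumexp(logp)


def oracle_map_path(counts_n, counts_c, params, floor=1e-10):
    paths, logp = enumerate_paths(counts_n, counts_c, params, floor)
    return paths[int(np.argmax(logp))]  # argmax takes the first max = lowest path

def oracle_marginals(counts_n, counts_c, params, floor=1e-10):
    """(M, 8) posterior marginals and list of (M-1) 8x8 pairwise posteriors."""
    paths, logp = enumerate_paths(counts_n, counts_c, params, floor)
    w = np.exp(logp - logsumexp(logp))
    M = paths.shape[1]
    gamma = np.zeros((M, 8))
    xi = [np.zeros((8, 8)) for _ in range(M - 1)]
    for p, weight in zip(paths, w):
        for i in range(M):
            gamma[i, p[i]] += weight
        for i in range(1, M):
            xi[i - 1][p[i - 1], p[i]] += weight
    return gamma, xi


def oracle_first_layer_paths(counts, params, floor=1e-10):
    """All-path log P(X, path) for the 2-state cohort HMM (M <= ~12)."""
    B = np.maximum(params.B, floor)
    K = B.shape[1] - 1
    M = counts.shape[0]
    logB = np.log(B)
    logem = np.zeros((M, 2))
    for i in range(M):
        for d in (0, 1):
            for x in counts[i]:
                logem[i, d] += logB[d, min(int(x), K)]
    lpi = np.log(np.maximum([1 - params.tau, params.tau], floor))
    lA = np.log(np.maximum(params.A, floor))
    paths = np.array(list(itertools.product(range(2), repeat=M)), dtype=np.int64)
    logp = lpi[paths[:, 0]] + logem[0][paths[:, 0]]
    for i in range(1, M):
        logp = logp + lA[paths[:, i - 1], paths[:, i]] + logem[i][paths[:, i]]
    return paths, logp


def random_model_params(rng, K=3, eps=0.0):
    """A random valid parameter set (Dirichlet rows, uniform weights)."""
    from bimmer.params import FirstLayerParams, ModelParams, SecondLayerParams

    def layer():
        return FirstLayerParams(
            tau=rng.uniform(0.05, 0.95),
            A=rng.dirichlet(np.ones(2) * 2, size=2),
            B=rng.dirichlet(np.ones(K + 1), size=2),
        )

    return ModelParams(
        normal=layer(),
        cancer=layer(),
        second=SecondLayerParams(
            tau_dm=rng.uniform(0.05, 0.95),
            A_dm=rng.dirichlet(np.ones(2) * 2, size=2),
            alpha=rng.uniform(0.05, 0.95),
        ),
        coupling_eps=eps,
    )
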