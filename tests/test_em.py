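"""Joint-chain forward-backward, M-steps, EM fitting and Viterbi decoding."""

import numpy as np
import pytest

from bimmer import em, first_layer, simulate
from bimmer.model import STATE_TRIPLES
from bimmer.params import SecondLayerParams

from conftest import random_counts
from oracles import (
    enumerate_paths as oracle_enumerate,
    oracle_initial,
    oracle_loglik,
    oracle_marginals,
    oracle_transition,
    random_model_params,
)


def sticky_init(alpha):
    return SecondLayerParams(
        tau_dm=1e-5, A_dm=np.array([[0.9, 0.1], [0.1, 0.9]]), alpha=alpha
    )


class TestForwardBackward:
    def test_loglik_matches_enumeration(self, rng):
        for trial in range(10):
            M = int(rng.integers(1, 7))
            p = random_model_params(rng)
            xn, xc = random_counts(rng, M)
            post = em.forward_backward(xn, xc, p)
            expect = oracle_loglik(xn, xc, p)
            assert post.loglik == pytest.approx(expect, abs=1e-9)

    def test_marginals_match_enumeration(self, rng):
        p = random_model_params(rng)
        xn, xc = random_counts(rng, 5)
        post = em.forward_backward(xn, xc, p)
        gamma, xi = oracle_marginals(xn, xc, p)
        np.testing.assert_allclose(post.gamma, gamma, atol=1e-9)
        for i in range(1, 5):
            np.testing.assert_allclose(post.pairwise(i), xi[i - 1], atol=1e-9)
        np.testing.assert_allclose(post.xi_sum, sum(xi), atol=1e-9)

    def test_gamma_rows_normalized(self, small_dataset):
        p = small_dataset.config.params
        post = em.forward_backward(small_dataset.counts_n, small_dataset.counts_c, p)
        np.testing.assert_allclose(post.gamma.sum(axis=1), 1.0, atol=1e-9)

    def test_pairwise_marginalizes_to_gamma(self, rng):
        p = random_model_params(rng)
        xn, xc = random_counts(rng, 6)
        post = em.forward_backward(xn, xc, p)
        for i in range(1, 6):
            xi = post.pairwise(i)
            np.testing.assert_allclose(xi.sum(axis=1), post.gamma[i - 1], atol=1e-9)
            np.testing.assert_allclose(xi.sum(axis=0), post.gamma[i], atol=1e-9)

    def test_alpha_one_decouples_dm_from_data(self, rng):
        """With alpha=1 the dm chain touches no observation, so its posterior
        equals its prior chain marginal."""
        p = random_model_params(rng)
        p.second.alpha = 1.0
        M = 30
        xn, xc = random_counts(rng, M)
        post = em.forward_backward(xn, xc, p)
        got = em.dm_posterior_score(post)
        prior = np.empty(M)
        v = np.array([1 - p.second.tau_dm, p.second.tau_dm])
        for i in range(M):
            prior[i] = v[1]
            v = v @ p.second.A_dm
        np.testing.assert_allclose(got, prior, atol=1e-9)

    def test_rejects_empty(self, rng):
        p = random_model_params(rng)
        with pytest.raises(ValueError):
            em.forward_backward(np.empty((0, 2)), np.empty((0, 2)), p)


class TestMStepTauAdm:
    def test_hard_posterior_recovers_empirical_frequencies(self, rng):
        """Posterior concentrated on one dm chain -> A_dm equals that chain's
        transition frequencies."""
        ds = simulate.simulate_dataset(
            simulate.SimulationConfig(
                M=400, n_normal=3, n_cancer=3, seed=9,
                params=simulate.reference_params(alpha=0.0, dm_self=(0.8, 0.6), tau=0.3),
            )
        )
        # posterior under the true (hard-coupled) parameters: dm is a
        # deterministic function of (mn, mc); with near-noiseless emissions it
        # concentrates, so test the identity through a high-confidence fit
        post = em.forward_backward(ds.counts_n, ds.counts_c, ds.config.params)
        tau_dm, A_dm = em.m_step_tau_adm(post, prev=ds.config.params.second)
        np.testing.assert_allclose(A_dm.sum(axis=1), 1.0, atol=1e-12)
        dm_hat, _, _ = em.viterbi_joint(ds.counts_n, ds.counts_c, ds.config.params)
        if dm_hat[:-1].sum() and (1 - dm_hat[:-1]).sum():
            emp = np.array(
                [
                    np.mean(dm_hat[1:][dm_hat[:-1] == 0]),
                    np.mean(dm_hat[1:][dm_hat[:-1] == 1]),
                ]
            )
            np.testing.assert_allclose(A_dm[:, 1], emp, atol=0.1)

    def test_unvisited_state_keeps_previous_row(self, rng):
        p = random_model_params(rng)
        p.second.tau_dm = 0.0
        p.second.A_dm = np.array([[1.0, 0.0], [0.5, 0.5]])  # dm=1 unreachable
        xn, xc = random_counts(rng, 20)
        post = em.forward_backward(xn, xc, p)
        with pytest.warns(RuntimeWarning):
            _, A_dm = em.m_step_tau_adm(post, prev=p.second)
        np.testing.assert_array_equal(A_dm[1], [0.5, 0.5])

    def test_single_em_step_increases_loglik(self, rng):
        for trial in range(5):
            p = random_model_params(rng)
            xn, xc = random_counts(rng, 40, 3, 3)
            post = em.forward_backward(xn, xc, p)
            tau_dm, A_dm = em.m_step_tau_adm(post, prev=p.second)
            alpha = em.m_step_alpha(post, p)
            from bimmer.params import ModelParams

            p2 = ModelParams(
                normal=p.normal, cancer=p.cancer,
                second=SecondLayerParams(tau_dm=tau_dm, A_dm=A_dm, alpha=alpha),
                coupling_eps=p.coupling_eps,
            )
            post2 = em.forward_backward(xn, xc, p2)
            assert post2.loglik >= post.loglik - 1e-9


class TestMStepAlpha:
    def grid_argmax(self, xn, xc, p, step=1e-4):
        """Independent oracle: Q(alpha) from enumeration posteriors, dense grid."""
        gamma, xi = oracle_marginals(xn, xc, p)
        xi_sum = sum(xi) if xi else np.zeros((8, 8))
        grid = np.arange(step, 1.0, step)
        best, best_q = 0.0, -np.inf
        for a in grid:
            p_try = type(p)(
                normal=p.normal, cancer=p.cancer,
                second=SecondLayerParams(
                    tau_dm=p.second.tau_dm, A_dm=p.second.A_dm, alpha=float(a)
                ),
                coupling_eps=p.coupling_eps,
            )
            with np.errstate(divide="ignore"):
                lT = np.log(np.maximum(oracle_transition(p_try), 1e-300))
                lpi = np.log(np.maximum(oracle_initial(p_try), 1e-300))
            qv = float(np.sum(xi_sum * lT) + gamma[0] @ lpi)
            if qv > best_q:
                best_q, best = qv, float(a)
        return best

    def test_newton_matches_grid_oracle(self, rng):
        for trial in range(20):
            M = int(rng.integers(2, 6))
            p = random_model_params(rng)
            xn, xc = random_counts(rng, M, 2, 2)
            post = em.forward_backward(xn, xc, p)
            got = em.m_step_alpha(post, p)
            expect = self.grid_argmax(xn, xc, p)
            assert abs(got - expect) < 1e-3

    def test_flat_objective_returns_current_alpha(self):
        """When every mixture leg pair coincides the Q surface is flat in
        alpha and the current value is kept."""
        p = random_model_params(np.random.default_rng(0))
        # An rows equal to the coupling value seen from every reachable state:
        # make mn deterministic and its transition rows match the indicator
        p.normal.A = np.array([[1.0, 0.0], [0.0, 1.0]])
        p.normal.tau = 0.0
        p.cancer.tau = 0.0
        p.cancer.A = np.eye(2)
        p.second.tau_dm = 0.0
        p.second.A_dm = np.eye(2)
        p.second.alpha = 0.37
        xn = np.zeros((5, 1), dtype=int)
        xc = np.zeros((5, 1), dtype=int)
        post = em.forward_backward(xn, xc, p)
        assert em.m_step_alpha(post, p) == pytest.approx(0.37)

    def test_result_always_in_unit_interval(self, rng):
        for trial in range(5):
            p = random_model_params(rng)
            xn, xc = random_counts(rng, 15)
            post = em.forward_backward(xn, xc, p)
            a = em.m_step_alpha(post, p)
            assert 0.0 <= a <= 1.0


class TestFit:
    def test_monotone_loglik_on_random_fixtures(self, rng):
        for trial in range(5):
            p = random_model_params(rng, K=5)
            xn, xc = random_counts(rng, 120, 3, 3, K=5)
            nres = first_layer.baum_welch(xn, K=5, max_iter=20)
            cres = first_layer.baum_welch(xc, K=5, max_iter=20)
            state = em.fit(xn, xc, nres.params, cres.params, max_iter=25, tol=0.0)
            assert np.all(np.diff(state.loglik_trace) > -1e-6)
            assert np.all((state.alpha_trace >= 0) & (state.alpha_trace <= 1))

    def test_near_fixed_point_at_truth_on_consistent_data(self):
        """Hard-coupled data initialized at the generating parameters is
        already near a stationary point: EM converges almost immediately and
        barely moves the estimates (on finite data the truth is close to,
        not exactly at, the MLE)."""
        truth = simulate.reference_params(alpha=0.0, tau=0.2)
        ds = simulate.simulate_dataset(
            simulate.SimulationConfig(M=800, n_normal=4, n_cancer=4, seed=13, params=truth)
        )
        state = em.fit(
            ds.counts_n, ds.counts_c, truth.normal, truth.cancer,
            init=truth.second, max_iter=20,
        )
        assert state.converged
        assert state.second.alpha < 0.01  # stays pinned at the boundary truth
        np.testing.assert_allclose(state.second.A_dm, truth.second.A_dm, atol=0.05)
        # total likelihood gain from the truth start is tiny per bin
        gain = state.loglik_trace[-1] - state.loglik_trace[0]
        assert 0 <= gain < 0.01 * 800

    def test_alpha_recovery_and_init_robustness(self):
        """Moderate-scale recovery: both inits agree and land near truth."""
        truth = simulate.reference_params(alpha=0.2)
        ds = simulate.simulate_dataset(
            simulate.SimulationConfig(M=20_000, n_normal=8, n_cancer=8, seed=3, params=truth)
        )
        nres = first_layer.baum_welch(ds.counts_n)
        cres = first_layer.baum_welch(ds.counts_c)
        s_lo = em.fit(ds.counts_n, ds.counts_c, nres.params, cres.params,
                      init=sticky_init(0.01))
        s_hi = em.fit(ds.counts_n, ds.counts_c, nres.params, cres.params,
                      init=sticky_init(0.3))
        assert abs(s_lo.second.alpha - s_hi.second.alpha) < 0.01
        assert abs(s_lo.second.alpha - 0.2) < 0.05
        assert abs(s_lo.second.A_dm[1, 1] - 0.71) < 0.05

    def test_aborts_on_nonfinite(self, rng):
        # emissions with an impossible category and no flooring would be -inf;
        # the public path floors, so force the failure through a poisoned track
        p = random_model_params(rng)
        with pytest.raises((FloatingPointError, ValueError)):
            em.fit(
                np.full((10, 2), -1), np.zeros((10, 2), dtype=int),
                p.normal, p.cancer,
            )


class TestViterbiJoint:
    def test_matches_exhaustive_search(self, rng):
        for trial in range(10):
            M = int(rng.integers(1, 7))
            p = random_model_params(rng)
            xn, xc = random_counts(rng, M)
            dm, mc, mn = em.viterbi_joint(xn, xc, p)
            paths, logp = oracle_enumerate(xn, xc, p)
            got = 4 * dm + 2 * mc + mn
            got_lp = logp[int(np.ravel_multi_index(tuple(got), (8,) * M))]
            # the decoded path attains the brute-force optimum (ties within
            # accumulation noise are equally valid decodes)
            assert got_lp == pytest.approx(logp.max(), abs=1e-9)

    def test_alpha_zero_path_respects_coupling(self):
        truth = simulate.reference_params(alpha=0.0)
        ds = simulate.simulate_dataset(
            simulate.SimulationConfig(M=3_000, n_normal=4, n_cancer=4, seed=21, params=truth)
        )
        dm, mc, mn = em.viterbi_joint(ds.counts_n, ds.counts_c, truth)
        np.testing.assert_array_equal(mn, mc ^ dm)

    def test_beats_baselines_on_default_scenario(self, small_dataset):
        from bimmer import evaluate

        ds = small_dataset
        nres = first_layer.baum_welch(ds.counts_n)
        cres = first_layer.baum_welch(ds.counts_c)
        state = em.fit(ds.counts_n, ds.counts_c, nres.params, cres.params)
        post = em.forward_backward(ds.counts_n, ds.counts_c, state.params)
        score = em.dm_posterior_score(post)
        auc_b = evaluate.pr_roc_auc(score, ds.truth_dm).auc_roc
        auc_w = evaluate.pr_roc_auc(
            1 - evaluate.per_bin_wilcoxon(ds.counts_n, ds.counts_c), ds.truth_dm
        ).auc_roc
        assert auc_b > auc_w


class TestPosteriorScore:
    def test_complementary_scores_sum_to_one(self, small_dataset):
        p = small_dataset.config.params
        post = em.forward_backward(small_dataset.counts_n, small_dataset.counts_c, p)
        s1 = em.dm_posterior_score(post)
        s0 = post.gamma[:, :4].sum(axis=1)
        np.testing.assert_allclose(s0 + s1, 1.0, atol=1e-9)

    def test_score_tracks_viterbi_calls(self, small_dataset):
        ds = small_dataset
        p = ds.config.params
        post = em.forward_backward(ds.counts_n, ds.counts_c, p)
        score = em.dm_posterior_score(post)
        dm, _, _ = em.viterbi_joint(ds.counts_n, ds.counts_c, p)
        if dm.sum() and (1 - dm).sum():
            assert score[dm == 1].mean() > score[dm == 0].mean()

    def test_neighbor_smoothing_inside_dm_run(self):
        """A locally uninformative bin inside a long differential stretch
        still scores above 0.5 because adjacent bins share the dm state."""
        from bimmer.params import FirstLayerParams, ModelParams, SecondLayerParams

        # emission pmfs whose category 2 is equally likely in both states, so
        # a bin full of 2s carries no evidence about any chain
        Bn = np.array([[0.70, 0.15, 0.10, 0.05], [0.15, 0.50, 0.10, 0.25]])
        Bc = np.array([[0.80, 0.10, 0.06, 0.04], [0.20, 0.50, 0.06, 0.24]])
        truth = ModelParams(
            normal=FirstLayerParams(1e-5, np.array([[0.66, 0.34], [0.08, 0.92]]), Bn),
            cancer=FirstLayerParams(1e-5, np.array([[0.76, 0.24], [0.03, 0.97]]), Bc),
            second=SecondLayerParams(1e-5, np.array([[0.97, 0.03], [0.29, 0.71]]), 0.0),
        )
        M = 41
        dm = np.zeros(M, dtype=int)
        dm[10:31] = 1
        mc = np.zeros(M, dtype=int)
        mn = mc ^ dm
        rng = np.random.default_rng(5)
        xn, xc = simulate.simulate_counts(mn, mc, Bn, Bc, 6, 6, 0.0, rng)
        mid = 20
        xn[mid] = xc[mid] = 2  # equal-likelihood category: no per-bin evidence
        post = em.forward_backward(xn, xc, truth)
        score = em.dm_posterior_score(post)
        assert score[mid] > 0.5
        assert score[dm == 1].mean() > score[dm == 0].mean()
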