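"""The Gibbs sampler: pseudo-likelihood, conditional updates, summaries."""

import math

import numpy as np
import pandas as pd
import pytest

from bmrfnet import (
    CARParameters,
    EdgePriorSpec,
    ExpressionMatrix,
    MCMCConfig,
    PrecisionMatrix,
    SSLPrior,
    gamma_conditional_probability,
    log_pseudo_likelihood,
    run_mcmc,
    sample_mvn,
    select_network,
    standardize,
    summarize_edges,
)
from bmrfnet.sampler import EdgePosterior

from _oracles import batch_means_se, posterior_gamma_oracle, pseudo_loglik_loop


def std_noise(n, p, seed):
    return standardize(
        ExpressionMatrix(np.random.default_rng(seed).normal(size=(n, p)))
    )


class TestLogPseudoLikelihood:
    def test_zero_beta_closed_form(self):
        x = std_noise(40, 3, 0)
        car = CARParameters(np.zeros((3, 3)), np.ones(3))
        expected = -(40 * 3 / 2) * math.log(2 * math.pi) - 0.5 * np.sum(x.values**2)
        assert log_pseudo_likelihood(x, car) == pytest.approx(expected)

    def test_matches_double_loop_oracle(self, rng):
        x = std_noise(25, 4, 1)
        beta = rng.normal(scale=0.2, size=(4, 4))
        beta = 0.5 * (beta + beta.T)
        np.fill_diagonal(beta, 0.0)
        sigma2 = rng.uniform(0.5, 2.0, size=4)
        got = log_pseudo_likelihood(x, CARParameters(beta, sigma2))
        assert got == pytest.approx(pseudo_loglik_loop(x.values, beta, sigma2), abs=1e-10)

    def test_invariant_to_sample_permutation(self, rng):
        x = std_noise(30, 3, 2)
        car = CARParameters(np.zeros((3, 3)), np.full(3, 1.3))
        perm = rng.permutation(30)
        x2 = ExpressionMatrix(
            x.values[perm], gene_ids=x.gene_ids, standardized=True
        )
        assert log_pseudo_likelihood(x, car) == pytest.approx(
            log_pseudo_likelihood(x2, car)
        )

    def test_rejects_bad_variance(self):
        with pytest.raises(ValueError, match="positive"):
            CARParameters(np.zeros((2, 2)), np.array([1.0, -1.0]))


class TestGammaConditional:
    def test_at_zero_beta_spike_dominates(self):
        # psi1(0)/psi0(0) = tau1/tau0 = 1/10, so P = 0.5/(0.5 + 5) = 1/11
        p = gamma_conditional_probability(0.0, 0.5, SSLPrior(2.0, 20.0))
        assert p == pytest.approx(1.0 / 11.0)

    def test_degenerate_prior_probabilities(self):
        assert gamma_conditional_probability(0.7, 1.0, SSLPrior()) == 1.0
        assert gamma_conditional_probability(0.7, 0.0, SSLPrior()) == 0.0

    def test_monotone_in_magnitude(self):
        prior = SSLPrior(2.0, 20.0)
        probs = [
            gamma_conditional_probability(b, 0.5, prior)
            for b in np.linspace(0.0, 1.0, 25)
        ]
        assert np.all(np.diff(probs) > 0)


class TestRunMcmc:
    def test_same_seed_identical_draws(self):
        x = std_noise(40, 4, 3)
        pri = EdgePriorSpec.noninformative(4)
        cfg = MCMCConfig(n_iter=600, burn_in=200, seed=5)
        a = run_mcmc(x, pri, config=cfg)
        b = run_mcmc(x, pri, config=cfg)
        assert np.array_equal(a.beta_draws, b.beta_draws)
        assert np.array_equal(a.gamma_draws, b.gamma_draws)
        assert np.array_equal(a.sigma2_draws, b.sigma2_draws)

    def test_draw_shapes_and_candidate_restriction(self):
        x = std_noise(40, 4, 4)
        from bmrfnet import NetworkGraph

        cand = NetworkGraph.from_edges(4, [(0, 1), (2, 3)])
        pri = EdgePriorSpec.noninformative(4, candidate_mask=cand)
        s = run_mcmc(x, pri, config=MCMCConfig(n_iter=400, burn_in=100, seed=1))
        assert s.n_pairs == 2
        assert list(zip(s.pair_j, s.pair_k)) == [(0, 1), (2, 3)]
        assert set(np.unique(s.gamma_draws)) <= {0, 1}
        assert s.beta_draws.shape == s.p_draws.shape == (300, 2)

    def test_thinning_counts(self):
        x = std_noise(30, 3, 5)
        s = run_mcmc(
            x,
            EdgePriorSpec.noninformative(3),
            config=MCMCConfig(n_iter=1000, burn_in=400, thin=3, seed=0),
        )
        assert s.n_retained == 200

    def test_requires_standardized_data(self):
        x = ExpressionMatrix(np.random.default_rng(0).normal(size=(20, 3)))
        with pytest.raises(ValueError, match="standardized"):
            run_mcmc(x, EdgePriorSpec.noninformative(3))

    def test_exact_gibbs_and_metropolis_agree(self):
        # both kernels target the same posterior on a 2-node problem
        om = PrecisionMatrix(np.array([[1.0, 0.3], [0.3, 1.0]]))
        x = standardize(sample_mvn(om, 30, seed=11))
        pri = EdgePriorSpec.noninformative(2)
        pg = run_mcmc(
            x, pri, config=MCMCConfig(n_iter=25_000, burn_in=5_000, seed=2)
        ).gamma_draws[:, 0].astype(float)
        pm = run_mcmc(
            x,
            pri,
            config=MCMCConfig(
                n_iter=25_000, burn_in=5_000, seed=3, beta_update="metropolis"
            ),
        ).gamma_draws[:, 0].astype(float)
        se = math.hypot(batch_means_se(pg), batch_means_se(pm))
        assert abs(pg.mean() - pm.mean()) < 3 * se + 0.005


class TestDetailedBalance:
    def test_two_node_chain_matches_enumeration_oracle(self):
        """On p=2, n=30 the chain's P(gamma=1) agrees with the
        enumeration-plus-quadrature oracle within Monte-Carlo error."""
        om = PrecisionMatrix(np.array([[1.0, 0.3], [0.3, 1.0]]))
        x = standardize(sample_mvn(om, 30, seed=11))
        oracle = posterior_gamma_oracle(x.values)[0]
        s = run_mcmc(
            x,
            EdgePriorSpec.noninformative(2),
            config=MCMCConfig(n_iter=25_000, burn_in=5_000, seed=2),
        )
        draws = s.gamma_draws[:, 0].astype(float)
        se = batch_means_se(draws)
        assert abs(draws.mean() - oracle) < 3 * se + 0.005


class TestSummarizeEdges:
    def make_samples(self, gamma, beta=None):
        from bmrfnet.sampler import PosteriorSamples

        gamma = np.asarray(gamma, dtype=np.int8)
        n_keep, m = gamma.shape
        beta = np.zeros((n_keep, m)) if beta is None else beta
        return PosteriorSamples(
            pair_j=np.array([0, 0]),
            pair_k=np.array([1, 2]),
            gene_ids=["a", "b", "c"],
            beta_draws=beta,
            gamma_draws=gamma,
            sigma2_draws=np.ones((n_keep, 3)),
            p_draws=np.full((n_keep, m), 0.5),
            loglik_trace=np.zeros(n_keep),
        )

    def test_all_ones_gives_probability_one(self):
        s = self.make_samples(np.ones((150, 2)))
        ep = summarize_edges(s)
        assert np.all(ep.table["existence_probability"] == 1.0)

    def test_threshold_selection_and_monotonicity(self):
        gamma = np.zeros((200, 2), dtype=int)
        gamma[:120, 0] = 1  # probability 0.6
        gamma[:80, 1] = 1  # probability 0.4
        s = self.make_samples(gamma)
        ep = summarize_edges(s, threshold=0.5)
        assert ep.table["selected"].tolist() == [True, False]
        for lo, hi in [(0.1, 0.3), (0.3, 0.7), (0.5, 0.9)]:
            n_lo = summarize_edges(s, threshold=lo).n_selected
            n_hi = summarize_edges(s, threshold=hi).n_selected
            assert n_hi <= n_lo

    def test_too_few_draws_rejected(self):
        s = self.make_samples(np.ones((50, 2)))
        with pytest.raises(ValueError, match="100"):
            summarize_edges(s)

    def test_beta_quantiles_are_marginal(self, rng):
        beta = rng.normal(0.3, 0.05, size=(500, 2))
        s = self.make_samples(np.ones((500, 2)), beta=beta)
        ep = summarize_edges(s)
        assert ep.table["beta_mean"].to_numpy() == pytest.approx(
            beta.mean(axis=0)
        )
        assert np.all(ep.table["beta_q025"] < ep.table["beta_median"])
        assert np.all(ep.table["beta_median"] < ep.table["beta_q975"])


class TestSelectNetwork:
    def _edge_posterior(self, probs, threshold=0.5):
        m = len(probs)
        table = pd.DataFrame(
            {
                "gene_i": [f"g{j}" for j in range(m)],
                "gene_j": [f"g{j + 1}" for j in range(m)],
                "existence_probability": probs,
                "beta_mean": np.zeros(m),
                "beta_q025": np.zeros(m),
                "beta_median": np.zeros(m),
                "beta_q975": np.zeros(m),
                "selected": np.asarray(probs) > threshold,
                "_j": np.arange(m),
                "_k": np.arange(1, m + 1),
            }
        )
        return EdgePosterior(
            table=table,
            threshold=threshold,
            p=m + 1,
            gene_ids=[f"g{j}" for j in range(m + 1)],
        )

    def test_none_above_threshold_gives_empty_graph(self):
        net = select_network(self._edge_posterior([0.1, 0.2, 0.3]))
        assert net.n_edges == 0

    def test_all_above_threshold_returns_candidates(self):
        net = select_network(self._edge_posterior([0.9, 0.8, 0.7]))
        assert net.edges() == [(0, 1), (1, 2), (2, 3)]

    def test_probability_matrix_symmetric(self):
        ep = self._edge_posterior([0.9, 0.2])
        pm = ep.probability_matrix()
        assert np.array_equal(pm, pm.T)
        assert pm[0, 1] == 0.9


class TestParameterRecovery:
    def test_fixed_network_signs_and_nonedge_probabilities(self, m3_single_fit):
        """On the two-hub fixed network (edge partial correlation -0.216,
        hence true strength beta = -0.216), the posterior strength means on
        detected true edges are negative, and probabilities on true
        non-edges stay near zero."""
        truth, res = m3_single_fit
        tab = res.edges.table
        jj = tab["_j"].to_numpy()
        kk = tab["_k"].to_numpy()
        is_true = truth.adjacency[jj, kk].astype(bool)
        signs = np.sign(tab["beta_mean"].to_numpy()[is_true])
        assert (signs == -1).mean() >= 0.95
        pm = res.existence_probabilities
        ju, ku = np.triu_indices(truth.p, 1)
        nonedge = truth.adjacency[ju, ku] == 0
        assert pm[ju, ku][nonedge].mean() < 0.1
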