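"""Recovery metrics, Brier score and the replication harness."""

import numpy as np
import pandas as pd
import pytest

from bmrfnet import (
    NetworkGraph,
    SimulationSetting,
    MCMCConfig,
    brier_score,
    confusion_metrics,
    hub_edge_count,
    m3_fixture,
    run_replication_study,
)
from bmrfnet.sampler import EdgePosterior
import bmrfnet.evaluation as evaluation

from _oracles import brier_loop, confusion_loop


def random_graph_pair(rng, p=12):
    a = np.triu(rng.random((p, p)) < 0.2, 1).astype(int)
    b = np.triu(rng.random((p, p)) < 0.2, 1).astype(int)
    return NetworkGraph(a + a.T), NetworkGraph(b + b.T)


def edge_posterior_from_matrix(prob, threshold=0.5):
    p = prob.shape[0]
    j, k = np.triu_indices(p, 1)
    keep = prob[j, k] > 0
    j, k = j[keep], k[keep]
    pr = prob[j, k]
    m = j.size
    table = pd.DataFrame(
        {
            "gene_i": [f"g{x}" for x in j],
            "gene_j": [f"g{x}" for x in k],
            "existence_probability": pr,
            "beta_mean": np.zeros(m),
            "beta_q025": np.zeros(m),
            "beta_median": np.zeros(m),
            "beta_q975": np.zeros(m),
            "selected": pr > threshold,
            "_j": j,
            "_k": k,
        }
    )
    return EdgePosterior(
        table=table, threshold=threshold, p=p, gene_ids=[f"g{x}" for x in range(p)]
    )


class TestConfusionMetrics:
    def test_perfect_estimate(self):
        g = NetworkGraph.from_edges(5, [(0, 1), (2, 3)])
        r = confusion_metrics(g, g)
        assert (r.SEN, r.SPE, r.F1, r.MCC, r.FDR) == (1.0, 1.0, 1.0, 1.0, 0.0)

    def test_hand_computed_instance(self):
        # truth: 15 edges; estimate: 14 of them plus 2 false edges
        p = 25
        rng = np.random.default_rng(0)
        j, k = np.triu_indices(p, 1)
        order = rng.permutation(j.size)
        true_pairs = [(j[i], k[i]) for i in order[:15]]
        est_pairs = true_pairs[:14] + [(j[i], k[i]) for i in order[15:17]]
        truth = NetworkGraph.from_edges(p, true_pairs)
        est = NetworkGraph.from_edges(p, est_pairs)
        r = confusion_metrics(est, truth)
        assert r.TP == 14
        assert r.SEN == pytest.approx(14 / 15)
        assert r.FDR == pytest.approx(2 / 16)
        assert r.F1 == pytest.approx(2 * 14 / (2 * 14 + 2 + 1))

    def test_empty_estimate_conventions(self):
        truth = NetworkGraph.from_edges(4, [(0, 1)])
        r = confusion_metrics(NetworkGraph.empty(4), truth)
        assert (r.TP, r.FDR, r.F1, r.MCC) == (0, 0.0, 0.0, 0.0)

    def test_counts_partition_all_pairs(self, rng):
        est, truth = random_graph_pair(rng)
        r = confusion_metrics(est, truth)
        assert r.TP + r.FP + r.FN + r.TN == 12 * 11 // 2

    def test_matches_sklearn_on_random_instances(self, rng):
        from sklearn.metrics import f1_score, matthews_corrcoef

        for _ in range(25):
            est, truth = random_graph_pair(rng)
            r = confusion_metrics(est, truth)
            j, k = np.triu_indices(12, 1)
            y_pred = est.adjacency[j, k]
            y_true = truth.adjacency[j, k]
            assert r.F1 == pytest.approx(f1_score(y_true, y_pred, zero_division=0))
            assert r.MCC == pytest.approx(matthews_corrcoef(y_true, y_pred))

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError, match="mismatch"):
            confusion_metrics(NetworkGraph.empty(3), NetworkGraph.empty(4))


class TestBrierScore:
    def test_perfect_probabilities(self):
        truth = NetworkGraph.from_edges(4, [(0, 1), (2, 3)])
        ep = edge_posterior_from_matrix(truth.adjacency.astype(float))
        assert brier_score(ep, truth) == 0.0

    def test_all_half_gives_quarter(self):
        p = 5
        prob = np.full((p, p), 0.5)
        np.fill_diagonal(prob, 0.0)
        ep = edge_posterior_from_matrix(prob)
        truth = NetworkGraph.from_edges(p, [(0, 1)])
        assert brier_score(ep, truth) == pytest.approx(0.25)

    def test_noncandidate_pairs_count_as_zero_probability(self):
        truth = NetworkGraph.from_edges(4, [(0, 1), (1, 2)])
        prob = np.zeros((4, 4))
        prob[0, 1] = prob[1, 0] = 1.0  # only one candidate pair
        ep = edge_posterior_from_matrix(prob)
        # missed true edge (1,2) contributes a full unit of error over 6 pairs
        assert brier_score(ep, truth) == pytest.approx(1 / 6)

    def test_invariant_to_node_relabeling(self, rng):
        p = 8
        prob = np.triu(rng.random((p, p)), 1)
        prob = prob + prob.T
        est, truth = random_graph_pair(rng, p)
        perm = rng.permutation(p)
        ep = edge_posterior_from_matrix(prob)
        ep_perm = edge_posterior_from_matrix(prob[np.ix_(perm, perm)])
        truth_perm = NetworkGraph(truth.adjacency[np.ix_(perm, perm)])
        assert brier_score(ep_perm, truth_perm) == pytest.approx(
            brier_score(ep, truth)
        )


class TestHubEdgeCount:
    def test_empty_graph(self):
        assert hub_edge_count(NetworkGraph.empty(5), 2) == 0

    def test_m3_truth_hub_degrees(self):
        g, _ = m3_fixture()
        assert hub_edge_count(g, 1) == 14
        assert hub_edge_count(g, 3) == 7

    def test_bad_index(self):
        with pytest.raises(IndexError):
            hub_edge_count(NetworkGraph.empty(5), 5)


class TestReplicationStudy:
    SMALL = SimulationSetting("M1", p=10, S=0.1, n=60)
    FAST = MCMCConfig(n_iter=400, burn_in=200, seed=0)

    def test_reproducible_and_summary_shape(self):
        a = run_replication_study(
            self.SMALL, R=2, base_seed=7, methods=("BMRF.O",), mcmc=self.FAST
        )
        b = run_replication_study(
            self.SMALL, R=2, base_seed=7, methods=("BMRF.O",), mcmc=self.FAST
        )
        pd.testing.assert_frame_equal(a.records, b.records)
        summ = a.summary()
        assert ("F1", "mean") in summ.columns
        assert np.all(summ.loc[:, (slice(None), "se")] >= 0)

    def test_forced_identical_seeds_give_zero_se(self, monkeypatch):
        def same_seeds(base_seed, R):
            row = np.array([[123, 456, 789]])
            return np.repeat(row, R, axis=0)

        monkeypatch.setattr(evaluation, "_derive_seeds", same_seeds)
        study = run_replication_study(
            self.SMALL, R=2, base_seed=0, methods=("BMRF.O",), mcmc=self.FAST
        )
        summ = study.summary()
        assert float(summ.loc["BMRF.O", ("F1", "se")]) == 0.0
        assert float(summ.loc["BMRF.O", ("brier", "se")]) == 0.0

    def test_hub_degrees_recorded(self):
        setting = SimulationSetting("M3", p=50)
        study = run_replication_study(
            setting,
            R=2,
            base_seed=1,
            methods=("BMRF.O",),
            mcmc=MCMCConfig(n_iter=300, burn_in=150, seed=0),
            hub_nodes=(1, 3),
        )
        assert "hub_degree_1" in study.records.columns
        assert study.records["hub_degree_1"].notna().all()
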