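"""Log-linear Gaussian model, collapsed Gibbs sampler, exact enumeration oracle."""

import itertools

import networkx as nx
import numpy as np
import pytest
from scipy.stats import invgamma

from conftest import make_matrix
from gpinet import synthetic
from gpinet.bayesnet import (
    ModelParameters,
    NetworkStructure,
    PosteriorSummary,
    SamplerConfig,
    exact_posterior_small,
    expected_log_value,
    gibbs_sweep,
    load_posterior,
    log_joint,
    run_sampler,
    save_posterior,
)
from gpinet.datamodel import MatrixFormatError, NodeDescriptor, to_log_space


def structure_of(P, edges):
    nodes = [NodeDescriptor(f"n{i + 1}", "gene") for i in range(P)]
    adj = np.zeros((P, P), dtype=bool)
    for i, j in edges:
        adj[i, j] = True
    return NetworkStructure(nodes, adj)


def params_of(structure, beta_entries, sigma2):
    P = structure.n_nodes
    beta = np.zeros((P, P))
    for (i, j), b in beta_entries.items():
        beta[i, j] = b
    return ModelParameters(beta, np.asarray(sigma2, dtype=float))


def simulate_log(structure, params, n, seed):
    m = synthetic.simulate_condition(structure, params, n, seed=seed)
    return to_log_space(m)


class TestExpectedLogValue:
    def test_no_parents_empty_sum(self):
        st = structure_of(3, [])
        pa = params_of(st, {}, [1, 1, 1])
        assert expected_log_value(st, pa, np.array([5.0, 6.0, 7.0]), 0) == 0.0

    def test_single_parent(self):
        st = structure_of(2, [(0, 1)])
        pa = params_of(st, {(0, 1): 2.0}, [1, 1])
        assert expected_log_value(st, pa, np.array([0.5, 99.0]), 1) == pytest.approx(1.0)

    def test_opposite_parents_cancel(self):
        st = structure_of(3, [(0, 2), (1, 2)])
        pa = params_of(st, {(0, 2): 1.0, (1, 2): -1.0}, [1, 1, 1])
        assert expected_log_value(st, pa, np.array([0.7, 0.7, 0.0]), 2) == pytest.approx(0.0)

    def test_index_out_of_range(self):
        st = structure_of(2, [])
        pa = params_of(st, {}, [1, 1])
        with pytest.raises(IndexError):
            expected_log_value(st, pa, np.zeros(2), 5)


class TestLogJoint:
    def setup_method(self):
        self.config = SamplerConfig(n_iterations=10, n_burn_in=1)

    def test_matches_hand_formula_for_empty_structure(self):
        # all-zero log data, empty graph, unit variances: the likelihood is
        # pure Gaussian normalizing constants; priors evaluated independently
        P, N = 2, 4
        data = make_matrix(np.zeros((P, N)), space="log")
        st = structure_of(P, [])
        pa = params_of(st, {}, [1.0, 1.0])
        got = log_joint(data, st, pa, self.config)
        cfg = self.config
        expected = (
            -0.5 * N * P * np.log(2 * np.pi)
            + P * invgamma.logpdf(1.0, cfg.ig_shape, scale=cfg.ig_scale)
            + P * (P - 1) * np.log1p(-cfg.edge_prior)
        )
        assert got == pytest.approx(expected, rel=1e-12)

    def test_zero_beta_edge_changes_only_priors(self, rng):
        data = make_matrix(rng.normal(size=(2, 5)), space="log")
        st0 = structure_of(2, [])
        st1 = structure_of(2, [(0, 1)])
        sigma2 = [0.7, 1.3]
        pa0 = params_of(st0, {}, sigma2)
        pa1 = params_of(st1, {(0, 1): 0.0}, sigma2)
        cfg = self.config
        diff = log_joint(data, st1, pa1, cfg) - log_joint(data, st0, pa0, cfg)
        # beta prior density at 0 (variance tau^2 * sigma_1^2) + edge prior odds
        v = cfg.beta_prior_var * sigma2[1]
        expected = (
            -0.5 * np.log(2 * np.pi * v)
            + np.log(cfg.edge_prior) - np.log1p(-cfg.edge_prior)
        )
        assert diff == pytest.approx(expected, rel=1e-10)

    def test_cyclic_structure_rejected(self, rng):
        data = make_matrix(rng.normal(size=(2, 5)), space="log")
        st = structure_of(2, [(0, 1)])
        st.adjacency[1, 0] = True  # force a 2-cycle past construction
        pa = params_of(structure_of(2, [(0, 1)]), {(0, 1): 1.0}, [1, 1])
        assert log_joint(data, st, pa, self.config) == -np.inf

    def test_raw_space_rejected(self, small_raw_matrix):
        st = structure_of(3, [])
        pa = params_of(st, {}, [1, 1, 1])
        with pytest.raises(MatrixFormatError, match="log"):
            log_joint(small_raw_matrix, st, pa, self.config)


class TestGibbsSweep:
    def test_identical_seed_identical_trajectory(self, rng):
        st = synthetic.random_dag(4, 0.5, seed=1)
        pa = synthetic.random_params(st, seed=1)
        data = simulate_log(st, pa, 30, seed=2)
        cfg = SamplerConfig(n_iterations=10, n_burn_in=1, seed=0)
        state = (NetworkStructure.empty(data.nodes), pa)
        out1 = gibbs_sweep(state, data, cfg, np.random.default_rng(7))
        out2 = gibbs_sweep(state, data, cfg, np.random.default_rng(7))
        np.testing.assert_array_equal(out1[0].adjacency, out2[0].adjacency)
        np.testing.assert_array_equal(out1[1].beta, out2[1].beta)

    def test_returned_structure_is_acyclic_and_valid(self, rng):
        st = synthetic.random_dag(5, 0.6, seed=3)
        pa = synthetic.random_params(st, seed=3)
        data = simulate_log(st, pa, 20, seed=4)
        cfg = SamplerConfig(n_iterations=10, n_burn_in=1, seed=0)
        state = (NetworkStructure.empty(data.nodes), pa)
        for _ in range(5):
            state = gibbs_sweep(state, data, cfg, rng)
            # NetworkStructure construction re-validates acyclicity
            assert state[0].n_nodes == 5

    def test_strongly_coupled_pair_always_linked(self):
        st = structure_of(2, [(0, 1)])
        pa = params_of(st, {(0, 1): 1.0}, [0.2**2, 0.2**2])
        data = simulate_log(st, pa, 100, seed=5)
        cfg = SamplerConfig(n_iterations=500, n_burn_in=100, seed=1)
        summary = run_sampler(data, cfg)
        either = summary.edge_prob[0, 1] + summary.edge_prob[1, 0]
        assert either > 0.95


class TestRunSampler:
    def test_chain_recovery_matches_oracle(self):
        st = structure_of(3, [(0, 1), (1, 2)])
        pa = params_of(st, {(0, 1): 1.2, (1, 2): 1.2}, [0.04, 0.04, 0.04])
        data = simulate_log(st, pa, 150, seed=21)
        cfg = SamplerConfig(n_iterations=4000, n_burn_in=1000, seed=1)
        summary = run_sampler(data, cfg)
        assert summary.edge_prob[0, 1] > 0.9
        assert summary.edge_prob[1, 2] > 0.9
        assert summary.edge_prob[2, 0] < 0.2
        exact = exact_posterior_small(data, cfg)
        assert np.abs(summary.edge_prob - exact.edge_prob).max() < 0.05

    def test_pure_noise_stays_sparse_and_matches_oracle(self):
        st = structure_of(3, [])
        pa = params_of(st, {}, [1.0, 1.0, 1.0])
        data = simulate_log(st, pa, 50, seed=30)
        cfg = SamplerConfig(n_iterations=6000, n_burn_in=1000, seed=2,
                            edge_prior=0.1)
        summary = run_sampler(data, cfg)
        off = ~np.eye(3, dtype=bool)
        assert summary.edge_prob[off].mean() < 0.2
        exact = exact_posterior_small(data, cfg)
        assert np.abs(summary.edge_prob - exact.edge_prob).max() < 0.05

    def test_single_retained_sample_gives_binary_probs(self):
        st = structure_of(3, [])
        pa = params_of(st, {}, [1, 1, 1])
        data = simulate_log(st, pa, 10, seed=6)
        cfg = SamplerConfig(n_iterations=50, n_burn_in=49, seed=0)
        summary = run_sampler(data, cfg)
        assert summary.n_retained == 1
        assert set(np.unique(summary.edge_prob)) <= {0.0, 1.0}

    def test_seed_reproducibility_bit_identical(self):
        st = synthetic.random_dag(4, 0.5, seed=7)
        pa = synthetic.random_params(st, seed=7)
        data = simulate_log(st, pa, 30, seed=8)
        cfg = SamplerConfig(n_iterations=200, n_burn_in=50, seed=11)
        a = run_sampler(data, cfg)
        b = run_sampler(data, cfg)
        np.testing.assert_array_equal(a.edge_prob, b.edge_prob)
        np.testing.assert_array_equal(a.beta_mean, b.beta_mean)
        np.testing.assert_array_equal(a.neg_prob, b.neg_prob)

    def test_burn_in_validation(self):
        with pytest.raises(ValueError, match="n_burn_in"):
            SamplerConfig(n_iterations=100, n_burn_in=100)

    def test_all_sampled_structures_acyclic(self):
        # independent check with networkx on thinned structure samples
        st = synthetic.random_dag(6, 0.4, seed=9)
        pa = synthetic.random_params(st, seed=9)
        data = simulate_log(st, pa, 40, seed=10)
        cfg = SamplerConfig(n_iterations=300, n_burn_in=50, seed=3)
        summary = run_sampler(data, cfg, thin_structures=10)
        assert len(summary.structure_samples) >= 25
        for adj in summary.structure_samples:
            g = nx.DiGraph(zip(*np.nonzero(adj)))
            g.add_nodes_from(range(6))
            assert nx.is_directed_acyclic_graph(g)

    def test_max_parents_respected(self):
        st = synthetic.random_dag(6, 0.8, seed=12)
        pa = synthetic.random_params(st, seed=12)
        data = simulate_log(st, pa, 60, seed=13)
        cfg = SamplerConfig(n_iterations=200, n_burn_in=20, seed=4, max_parents=2)
        summary = run_sampler(data, cfg, thin_structures=5)
        for adj in summary.structure_samples:
            assert adj.sum(axis=0).max() <= 2

    def test_permutation_invariance_of_edge_probabilities(self):
        st = structure_of(3, [(0, 1), (1, 2)])
        pa = params_of(st, {(0, 1): 1.0, (1, 2): -1.0}, [0.09, 0.09, 0.09])
        data = simulate_log(st, pa, 80, seed=14)
        cfg = SamplerConfig(n_iterations=100, n_burn_in=10, seed=0)
        exact = exact_posterior_small(data, cfg)
        perm = [2, 0, 1]
        permuted = make_matrix(data.values[perm], space="log")
        exact_p = exact_posterior_small(permuted, cfg)
        np.testing.assert_allclose(
            exact_p.edge_prob[np.ix_(np.argsort(perm), np.argsort(perm))],
            exact.edge_prob, atol=1e-10,
        )


class TestFixedStructureConjugacy:
    def test_beta_posterior_matches_closed_form(self):
        # single fixed parent: sampled beta must match the NIG regression
        # posterior (Student-t marginal) within Monte-Carlo error
        st = structure_of(2, [(0, 1)])
        pa = params_of(st, {(0, 1): 1.0}, [0.25, 0.04])
        data = simulate_log(st, pa, 60, seed=15)
        cfg = SamplerConfig(n_iterations=4000, n_burn_in=0, seed=5)
        x, y = data.values
        lam = x @ x + 1.0 / cfg.beta_prior_var
        m_hat = x @ y / lam
        a_n = cfg.ig_shape + 30.0
        b_n = cfg.ig_scale + 0.5 * (y @ y - (x @ y) ** 2 / lam)
        exp_var = b_n / (a_n - 1) / lam

        draws = []
        rng = np.random.default_rng(cfg.seed)
        from gpinet.bayesnet import _Sampler
        sampler = _Sampler(data, cfg, structure=st, fixed_structure=True)
        for _ in range(cfg.n_iterations):
            sampler.sweep(rng)
            draws.append(sampler.beta[0, 1])
        draws = np.asarray(draws)
        M = draws.size
        mcse_mean = draws.std(ddof=1) / np.sqrt(M)
        assert abs(draws.mean() - m_hat) < 3 * mcse_mean
        v = draws.var(ddof=1)
        m4 = np.mean((draws - draws.mean()) ** 4)
        mcse_var = np.sqrt(max(m4 - v**2, 0.0) / M)
        assert abs(v - exp_var) < 3 * mcse_var


class TestExactPosteriorSmall:
    @pytest.mark.parametrize("P,count", [(2, 3), (3, 25)])
    def test_dag_counts(self, P, count):
        st = structure_of(P, [])
        pa = params_of(st, {}, [1.0] * P)
        data = simulate_log(st, pa, 10, seed=16)
        cfg = SamplerConfig(n_iterations=10, n_burn_in=1)
        summary = exact_posterior_small(data, cfg)
        assert summary.n_retained == count

    def test_dag_count_matches_brute_force_networkx(self):
        # independent enumeration of all 2^6 labelled digraphs on 3 nodes
        pairs = [(i, j) for i in range(3) for j in range(3) if i != j]
        n_dags = 0
        for bits in itertools.product([0, 1], repeat=6):
            g = nx.DiGraph()
            g.add_nodes_from(range(3))
            g.add_edges_from(p for p, b in zip(pairs, bits) if b)
            if nx.is_directed_acyclic_graph(g):
                n_dags += 1
        assert n_dags == 25

    def test_p_too_large_rejected(self, rng):
        data = make_matrix(rng.normal(size=(6, 10)), space="log")
        with pytest.raises(ValueError, match="P <= 5"):
            exact_posterior_small(data, SamplerConfig(n_iterations=2, n_burn_in=1))

    def test_edge_probabilities_sum_consistently(self):
        st = structure_of(2, [(0, 1)])
        pa = params_of(st, {(0, 1): 1.0}, [0.09, 0.04])
        data = simulate_log(st, pa, 40, seed=17)
        summary = exact_posterior_small(
            data, SamplerConfig(n_iterations=2, n_burn_in=1)
        )
        # three DAGs on two nodes: probabilities of the two orientations
        # cannot exceed 1 combined
        assert summary.edge_prob[0, 1] + summary.edge_prob[1, 0] <= 1.0 + 1e-12
        assert summary.edge_prob[0, 1] > 0.4  # strong coupling detected


class TestSerialization:
    def test_posterior_round_trip(self, tmp_path):
        st = synthetic.random_dag(4, 0.5, seed=18)
        pa = synthetic.random_params(st, seed=18)
        data = simulate_log(st, pa, 30, seed=19)
        cfg = SamplerConfig(n_iterations=100, n_burn_in=20, seed=6)
        summary = run_sampler(data, cfg)
        save_posterior(summary, tmp_path)
        back = load_posterior(tmp_path)
        np.testing.assert_allclose(back.edge_prob, summary.edge_prob, atol=1e-12)
        np.testing.assert_allclose(back.beta_mean, summary.beta_mean, atol=1e-12)
        assert back.n_retained == summary.n_retained
        assert back.config == summary.config
        assert [n.kind for n in back.nodes] == [n.kind for n in summary.nodes]
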