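"""Full conditionals, the Gibbs sweep contracts, likelihood evaluation and
variance-component updates."""

import numpy as np
import pytest
import scipy.stats

from carlm import (
    ChainState,
    HierarchicalModel,
    ModelSpec,
    SimulationParams,
    WardGraph,
    build_dataset,
    gibbs_sweep,
    icar_full_conditional,
    log_likelihood,
    make_lattice_graph,
    model_spec,
    run_chain,
    simulate_dataset,
)
from carlm.data import Dataset
from carlm.sampler import PriorSpec, VariancePrior, sample_variance, deviance


def _fixed_only_state(alpha, sigma2_e, beta=None):
    return ChainState(alpha=alpha, beta=beta, R=None, S=None,
                      sigma2_e=sigma2_e, sigma2_R=None, sigma2_S=None)


class TestICARFullConditional:
    def test_path_graph_middle_ward(self, path_graph):
        S = np.array([1.0, 99.0, 3.0])  # value at B irrelevant
        mean, var = icar_full_conditional(1, S, path_graph, sigma2_S=2.0)
        assert mean == 2.0 and var == 1.0

    def test_zero_neighbours_zero_mean(self, path_graph):
        mean, _ = icar_full_conditional(1, np.zeros(3), path_graph, 1.0)
        assert mean == 0.0

    def test_four_cycle(self, cycle4_graph):
        S = np.array([1.0, 2.0, 3.0, 4.0])
        mean, var = icar_full_conditional(0, S, cycle4_graph, sigma2_S=1.0)
        assert mean == 3.0  # (2 + 4) / 2
        assert var == 0.5

    def test_isolated_ward_errors(self):
        g = WardGraph.from_edges([("a", "b")], wards=["a", "b", "z"])
        with pytest.raises(ValueError, match="neighbours"):
            icar_full_conditional(2, np.zeros(3), g, 1.0)


class TestLogLikelihood:
    def test_unit_density_point(self):
        # N(0, 1/(2*pi)) has density exactly 1 at its mean
        ds = Dataset(np.array([2.0]), np.array([0]), None, np.array([1]))
        state = _fixed_only_state(alpha=2.0, sigma2_e=1.0 / (2 * np.pi))
        assert log_likelihood(state, ds) == pytest.approx(0.0, abs=1e-12)

    def test_additivity(self):
        one = Dataset(np.array([1.3]), np.array([0]), None, np.array([1]))
        two = Dataset(np.array([1.3, 1.3]), np.array([0, 0]), None, np.array([2]))
        s = _fixed_only_state(alpha=0.4, sigma2_e=2.2)
        assert log_likelihood(s, two) == pytest.approx(2 * log_likelihood(s, one))

    def test_matches_independent_density_sum(self, lattice_4x8):
        rng = np.random.default_rng(42)
        records, _ = simulate_dataset(lattice_4x8,
                                      SimulationParams(seed=9, mean_cases_per_ward=1.0))
        ds = build_dataset(records[:20], lattice_4x8)
        K = lattice_4x8.n_wards
        state = ChainState(alpha=rng.normal(), beta=rng.normal(size=8),
                           R=rng.normal(size=K), S=rng.normal(size=K),
                           sigma2_e=1.7, sigma2_R=1.0, sigma2_S=1.0)
        mu = (state.alpha + ds.covariates @ state.beta
              + state.R[ds.ward_index] + state.S[ds.ward_index])
        oracle = scipy.stats.norm.logpdf(ds.response, mu,
                                         np.sqrt(state.sigma2_e)).sum()
        assert log_likelihood(state, ds) == pytest.approx(oracle, abs=1e-10)
        assert deviance(state, ds) == pytest.approx(-2 * oracle, abs=1e-10)

    def test_nonpositive_variance_rejected(self):
        ds = Dataset(np.array([1.0]), np.array([0]), None, np.array([1]))
        with pytest.raises(ValueError):
            log_likelihood(_fixed_only_state(0.0, 0.0), ds)


class TestGibbsSweep:
    def test_model3_has_no_random_effect_blocks(self, path_graph, tiny_records):
        ds = build_dataset(tiny_records, path_graph)
        state = ChainState(0.0, np.zeros(8), None, None, 1.0, None, None)
        rng = np.random.default_rng(0)
        new = gibbs_sweep(state, ds, path_graph, model_spec("model3"),
                          PriorSpec(), rng)
        assert new.R is None and new.S is None
        assert new.sigma2_R is None and new.sigma2_S is None
        assert new.beta.shape == (8,)

    def test_spatial_sum_to_zero_after_each_sweep(self, lattice_4x8, simulated_32):
        records, _ = simulated_32
        ds = build_dataset(records, lattice_4x8)
        K = lattice_4x8.n_wards
        state = ChainState(4.0, np.zeros(8), np.zeros(K), np.zeros(K),
                           3.0, 0.05, 0.05)
        rng = np.random.default_rng(5)
        for _ in range(10):
            state = gibbs_sweep(state, ds, lattice_4x8, model_spec("model6"),
                                PriorSpec(), rng)
            assert abs(state.S.sum()) < 1e-10

    def test_intercept_only_matches_conjugate_posterior(self):
        # known sigma_e^2 = 1 and an effectively flat prior: the posterior
        # of alpha is exactly N(ybar, 1/n)
        rng = np.random.default_rng(21)
        y = rng.normal(2.0, 1.0, size=50)
        ds = Dataset(y, np.zeros(50, dtype=int), None, np.array([50]))
        g = WardGraph(("A",), ((),))
        spec = ModelSpec(False, False, False, "intercept_only")
        samples = run_chain(ds, g, spec, PriorSpec(fixed_effect_sd=1e6),
                            n_iter=4000, burn_in=100, n_chains=1, seed=8,
                            fixed_sigma2_e=1.0)
        draws = samples.alpha.reshape(-1)
        n = len(y)
        # draws are iid here, so Monte-Carlo errors are exact
        assert draws.mean() == pytest.approx(y.mean(), abs=4 / np.sqrt(n * len(draws)))
        assert draws.var(ddof=1) == pytest.approx(1 / n, rel=0.1)


class TestRunChain:
    def test_retention_arithmetic(self, path_graph, tiny_records):
        ds = build_dataset(tiny_records, path_graph)
        s = run_chain(ds, path_graph, model_spec("model3"), n_iter=1000,
                      burn_in=500, thin=5, n_chains=2, seed=1)
        assert s.n_retained == 100 and s.n_chains == 2

    def test_same_seed_identical_samples(self, path_graph, tiny_records):
        ds = build_dataset(tiny_records, path_graph)
        kwargs = dict(n_iter=300, burn_in=100, n_chains=2, seed=77)
        a = run_chain(ds, path_graph, model_spec("model2"), **kwargs)
        b = run_chain(ds, path_graph, model_spec("model2"), **kwargs)
        assert np.array_equal(a.alpha, b.alpha)
        assert np.array_equal(a.beta, b.beta)
        assert np.array_equal(a.deviance, b.deviance)

    def test_within_ward_exchangeability(self, lattice_4x8, simulated_32):
        # permuting individuals within wards leaves the sampler's
        # sufficient statistics, hence its draws, unchanged
        records, _ = simulated_32
        ds = build_dataset(records, lattice_4x8)
        perm = np.concatenate([
            np.random.default_rng(3).permutation(np.flatnonzero(ds.ward_index == k))
            for k in range(lattice_4x8.n_wards)
        ])
        ds_perm = Dataset(ds.response[perm], ds.ward_index[perm],
                          ds.covariates[perm], ds.n_per_ward,
                          ward_ids=ds.ward_ids)
        kwargs = dict(n_iter=200, burn_in=50, n_chains=1, seed=4)
        a = run_chain(ds, lattice_4x8, model_spec("model6"), **kwargs)
        b = run_chain(ds_perm, lattice_4x8, model_spec("model6"), **kwargs)
        assert np.allclose(a.alpha, b.alpha)
        assert np.allclose(a.sigma2_S, b.sigma2_S)

    def test_isolated_ward_policy(self, tiny_records):
        g = WardGraph.from_edges([("A", "B"), ("B", "C")],
                                 wards=["A", "B", "C", "D"])
        ds = build_dataset(tiny_records, g)
        with pytest.raises(ValueError, match="isolated"):
            run_chain(ds, g, model_spec("model6"), n_iter=20, burn_in=10)
        s = run_chain(ds, g, model_spec("model6"), n_iter=20, burn_in=10,
                      allow_isolated=True, seed=2)
        assert np.all(s.S[:, :, 3] == 0.0)


class TestVarianceUpdates:
    def test_prior_recovery_with_no_data(self):
        # Gibbs on (R, sigma_R) alone must reproduce the prior on sigma_R:
        # Uniform(0, 3) here, checked at the quartiles
        prior = VariancePrior(kind="uniform_sd", upper=3.0)
        rng = np.random.default_rng(10)
        K, draws = 6, []
        s2 = 1.0
        for _ in range(30_000):
            R = rng.standard_normal(K) * np.sqrt(s2)
            s2 = sample_variance(R @ R, K, prior, rng)
            draws.append(np.sqrt(s2))
        q = np.percentile(draws[2000:], [25, 50, 75])
        assert np.allclose(q, [0.75, 1.5, 2.25], atol=0.25)

    def test_gamma_precision_posterior_moments(self):
        # conjugate closed form: tau ~ Gamma(a + df/2, b + ss/2)
        prior = VariancePrior(kind="gamma_precision", shape=2.0, rate=3.0)
        rng = np.random.default_rng(11)
        ss, df = 14.0, 10
        taus = np.array([1.0 / sample_variance(ss, df, prior, rng)
                         for _ in range(40_000)])
        a, b = 2.0 + df / 2, 3.0 + ss / 2
        assert taus.mean() == pytest.approx(a / b, rel=0.02)
        assert taus.var(ddof=1) == pytest.approx(a / b ** 2, rel=0.05)

    def test_icar_variance_uses_rank_K_minus_components(self):
        # two components (3 + 3 wards): the pairwise-difference density has
        # precision power (K - c)/2 = 2, so given S the full conditional of
        # sigma_S^2 under the uniform-SD prior is the truncated
        # inverse-gamma with shape (K - c - 1)/2
        import networkx as nx
        g = WardGraph.from_edges(
            [("a", "b"), ("b", "c"), ("x", "y"), ("y", "z")],
            wards=["a", "b", "c", "x", "y", "z"])
        nxg = nx.Graph([("a", "b"), ("b", "c"), ("x", "y"), ("y", "z")])
        c = nx.number_connected_components(nxg)
        rank = g.n_wards - c
        assert rank == 4
        S = np.array([0.5, -0.2, -0.3, 1.0, 0.0, -1.0])
        ss = sum((S[i] - S[j]) ** 2 for i, j in g.edges)
        prior = VariancePrior(kind="uniform_sd", upper=100.0)
        rng = np.random.default_rng(12)
        draws = np.array([sample_variance(ss, rank, prior, rng)
                          for _ in range(20_000)])
        oracle = scipy.stats.invgamma(a=(rank - 1) / 2, scale=ss / 2)
        ks = scipy.stats.kstest(draws, oracle.cdf).statistic
        assert ks < 0.02

    def test_variance_ordering_monotone_recovery(self):
        # larger generating sigma_R must yield a larger posterior median
        graph = make_lattice_graph(4, 8)
        medians = []
        for level, sigma_R in enumerate((0.1, 0.6, 1.5)):
            params = SimulationParams(seed=100 + level, sigma_R=sigma_R,
                                      sigma_S=0.0, mean_cases_per_ward=25.0)
            records, _ = simulate_dataset(graph, params)
            m = HierarchicalModel.from_records(records, graph, model_spec("model2"))
            res = m.fit(n_iter=1500, burn_in=500, n_chains=1, seed=level)
            medians.append(float(np.median(res.samples.sigma2_R)))
        assert medians[0] < medians[1] < medians[2]
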