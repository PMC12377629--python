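"""Localized CAR machinery and the Metropolis-within-Gibbs fit."""

import numpy as np
import pytest
from scipy import stats

from frontiercar.carmodel import (ModelSpec, alpha_min, boundary_relative_risk,
                                  build_wstar, car_full_conditional,
                                  car_log_density, car_precision, fit_model,
                                  identify_boundaries, sample_car_prior)
from frontiercar.graph import AreaGraph
from frontiercar.hardship import DissimilaritySet
from frontiercar.simulate import ScenarioConfig, generate_lattice_study

from conftest import grid_graph

LN2 = np.log(2.0)


def _zset(graph, values, units="decile"):
    return DissimilaritySet(graph.edges, np.asarray(values, float), graph.K,
                            units=units)


class TestWstar:
    def test_zero_dissimilarity_full_weight(self, path_graph):
        Z = _zset(path_graph, [0, 0])
        assert np.allclose(build_wstar(path_graph, Z, alpha=1.3), 1.0)

    def test_knife_edge_half(self, path_graph):
        Z = _zset(path_graph, [1, 0])
        w = build_wstar(path_graph, Z, alpha=LN2)
        assert w[0] == pytest.approx(0.5)

    def test_printed_threshold_scale(self, path_graph):
        """alpha = 0.077 on the maximal decile gap gives weight ~ 1/2."""
        Z = _zset(path_graph, [9, 0])
        w = build_wstar(path_graph, Z, alpha=0.077)
        assert w[0] == pytest.approx(np.exp(-0.693), abs=1e-3)
        assert w[0] == pytest.approx(0.5, abs=1e-3)

    def test_monotone_nonincreasing_in_alpha(self, grid3x3_queen, rng):
        Z = _zset(grid3x3_queen, rng.integers(0, 10, size=20))
        prev = build_wstar(grid3x3_queen, Z, 0.01)
        for a in [0.05, 0.1, 0.5, 1.0, 5.0]:
            w = build_wstar(grid3x3_queen, Z, a)
            assert np.all(w <= prev + 1e-15)
            assert np.all((w > 0) & (w <= 1))
            prev = w


class TestAlphaMin:
    def test_decile_units(self, path_graph):
        assert alpha_min(_zset(path_graph, [9, 3])) == pytest.approx(0.0770, abs=5e-4)

    def test_normalized_units(self, path_graph):
        Z = _zset(path_graph, [1.0, 0.3], units="normalized")
        assert alpha_min(Z) == pytest.approx(0.6931, abs=5e-5)

    def test_max_two(self, path_graph):
        assert alpha_min(_zset(path_graph, [2, 1])) == pytest.approx(0.3466, abs=5e-5)

    def test_all_zero_errors(self, path_graph):
        with pytest.raises(ValueError, match="no boundary"):
            alpha_min(_zset(path_graph, [0, 0]))


def test_boundary_relative_risk_transform():
    assert boundary_relative_risk(0.0) == 1.0
    assert boundary_relative_risk(np.log(2.0)) == pytest.approx(2.0)


class TestCarOracle:
    """Conditionals and joint density vs a dense multivariate-normal oracle."""

    def _dense_setup(self, rng, K=4):
        g = AreaGraph(unit_ids=tuple(range(K)),
                      edges=tuple((i, i + 1) for i in range(K - 1)))
        Z = _zset(g, rng.integers(0, 10, size=K - 1))
        return g, Z

    def test_full_conditional_matches_gaussian_conditioning(self, rng):
        g, Z = self._dense_setup(rng)
        alpha, tau2, eps = 0.4, 0.7, 1e-3
        Q = car_precision(g, Z, alpha, eps)
        W = np.diag(np.diag(Q)) - Q + np.diag(np.full(4, -eps))  # recover W*
        np.fill_diagonal(W, 0.0)
        phi = rng.normal(size=4)
        cov = tau2 * np.linalg.inv(Q)
        for k in range(4):
            m, v = car_full_conditional(phi, k, W, tau2, eps)
            # oracle: condition the joint Gaussian N(0, cov) on the rest
            others = [i for i in range(4) if i != k]
            s12 = cov[k, others]
            s22 = cov[np.ix_(others, others)]
            m_or = float(s12 @ np.linalg.solve(s22, phi[others]))
            v_or = float(cov[k, k] - s12 @ np.linalg.solve(s22, s12))
            assert m == pytest.approx(m_or, abs=1e-8)
            assert v == pytest.approx(v_or, abs=1e-8)

    def test_joint_density_matches_mvn_oracle(self, rng):
        g, Z = self._dense_setup(rng, K=5)
        alpha, tau2, eps = 0.25, 1.3, 1e-3
        Q = car_precision(g, Z, alpha, eps)
        phi = rng.normal(size=5)
        ours = car_log_density(phi, g, Z, alpha, tau2, eps)
        oracle = stats.multivariate_normal(np.zeros(5), tau2 * np.linalg.inv(Q))
        assert ours == pytest.approx(oracle.logpdf(phi), abs=1e-8)

    def test_joint_equals_product_of_sequential_conditionals(self, rng):
        """On a 3-node graph, p(phi) = p(phi1) p(phi2|phi1) p(phi3|phi1,phi2)."""
        g = AreaGraph(unit_ids=("a", "b", "c"), edges=((0, 1), (1, 2)))
        Z = _zset(g, [2, 7])
        alpha, tau2, eps = 0.3, 0.9, 1e-3
        Q = car_precision(g, Z, alpha, eps)
        cov = tau2 * np.linalg.inv(Q)
        phi = rng.normal(size=3)
        logp = 0.0
        for k in range(3):
            past = list(range(k))
            mu_k = (cov[k, past] @ np.linalg.solve(cov[np.ix_(past, past)],
                                                   phi[past])
                    if past else 0.0)
            var_k = cov[k, k] - (cov[k, past] @ np.linalg.solve(
                cov[np.ix_(past, past)], cov[past, k]) if past else 0.0)
            logp += stats.norm.logpdf(phi[k], mu_k, np.sqrt(var_k))
        assert car_log_density(phi, g, Z, alpha, tau2, eps) == pytest.approx(
            logp, abs=1e-8)

    def test_prior_draw_density_matches_oracle(self, rng):
        g = grid_graph(5, 5)
        Z = _zset(g, rng.integers(0, 10, size=len(g.edges)))
        phi = sample_car_prior(g, Z, 0.3, 0.25, 1e-3, rng=42)
        Q = car_precision(g, Z, 0.3, 1e-3)
        oracle = stats.multivariate_normal(np.zeros(25),
                                           0.25 * np.linalg.inv(Q),
                                           allow_singular=False)
        assert car_log_density(phi, g, Z, 0.3, 0.25) == pytest.approx(
            oracle.logpdf(phi), abs=1e-8)

    def test_isolated_unit_conditional(self):
        g = AreaGraph(unit_ids=("a", "b", "c"), edges=((0, 1),))
        W = np.zeros((3, 3))
        W[0, 1] = W[1, 0] = 1.0
        m, v = car_full_conditional(np.array([1.0, 2.0, 3.0]), 2, W,
                                    tau2=0.5, eps=1e-3)
        assert m == 0.0
        assert v == pytest.approx(0.5 / 1e-3)

    def test_pairwise_smoothing_limit(self):
        g = AreaGraph(unit_ids=("a", "b"), edges=((0, 1),))
        W = np.array([[0.0, 1.0], [1.0, 0.0]])
        m, _ = car_full_conditional(np.array([0.0, 2.0]), 0, W,
                                    tau2=1.0, eps=1e-12)
        assert m == pytest.approx(2.0, abs=1e-9)


class TestIdentifyBoundaries:
    def _samples_with_alpha(self, graph, alpha_draws, spec=None):
        """Minimal PosteriorSamples carrying given alpha draws."""
        from frontiercar.carmodel import PosteriorSamples
        S = len(alpha_draws)
        spec = spec or ModelSpec(n_keep=S, thin=1, n_burn=0)
        return PosteriorSamples(
            beta=np.zeros((S, 1)), beta_names=("intercept",),
            phi=np.zeros((S, graph.K)), tau2=np.ones(S),
            alpha=np.asarray(alpha_draws, float), accept_rates={},
            spec=spec, unit_ids=graph.unit_ids)

    def test_all_zero_dissimilarity_never_flags(self, grid3x3_queen):
        Z = _zset(grid3x3_queen, np.zeros(20))
        s = self._samples_with_alpha(grid3x3_queen, np.full(200, 30.0))
        fr = identify_boundaries(s, grid3x3_queen, Z)
        assert fr.n_flagged == 0
        assert np.all(fr.probability == 0)

    def test_degenerate_alpha_ln2_closed_form(self):
        """At alpha = ln 2 exactly, flagged edges are those with z >= 2."""
        K = 11
        g = AreaGraph(unit_ids=tuple(range(K)),
                      edges=tuple((i, i + 1) for i in range(K - 1)))
        z = np.arange(10)  # 0..9 across the path's edges
        Z = _zset(g, z)
        s = self._samples_with_alpha(g, np.full(100, LN2))
        fr = identify_boundaries(s, g, Z)
        assert np.array_equal(fr.flagged, z >= 2)
        assert np.array_equal(fr.probability, (z >= 2).astype(float))

    def test_probability_is_mixture_over_draws(self):
        g = AreaGraph(unit_ids=("a", "b"), edges=((0, 1),))
        Z = _zset(g, [9])
        # half the draws above ln2/9, half below
        draws = np.concatenate([np.full(50, 0.05), np.full(50, 0.2)])
        fr = identify_boundaries(self._samples_with_alpha(g, draws), g, Z)
        assert fr.probability[0] == pytest.approx(0.5)


@pytest.fixture(scope="module")
def small_fit():
    """One short fit on a 10x10 sparse-count lattice, reused across tests."""
    cfg = ScenarioConfig(nrows=10, ncols=10, seed=3)
    graph, table, Z, truth = generate_lattice_study(cfg)
    spec = ModelSpec(covariates=("x1",), n_burn=400, n_keep=300, thin=1, seed=17)
    samples = fit_model(table, graph, Z, spec)
    return graph, table, Z, truth, spec, samples


class TestFitModel:
    def test_same_seed_identical(self, small_fit):
        graph, table, Z, truth, spec, samples = small_fit
        again = fit_model(table, graph, Z, spec)
        assert np.array_equal(again.beta, samples.beta)
        assert np.array_equal(again.phi, samples.phi)
        assert np.array_equal(again.tau2, samples.tau2)
        assert np.array_equal(again.alpha, samples.alpha)

    def test_posterior_samples_invariants(self, small_fit):
        *_, spec, samples = small_fit
        assert np.all(samples.tau2 > 0)
        assert np.all((samples.alpha > 0) & (samples.alpha < spec.alpha_upper))
        assert samples.n_draws == spec.n_keep
        assert np.allclose(samples.phi.mean(axis=1), 0.0, atol=1e-10)

    def test_likelihood_identity_vs_direct_oracle(self, small_fit):
        """Stored-draw log-likelihoods equal a from-scratch evaluation."""
        graph, table, Z, truth, spec, samples = small_fit
        ll = samples.pointwise_loglik(table)
        X = np.column_stack([np.ones(table.K),
                             table.covariates["x1"].to_numpy()])
        for s in [0, samples.n_draws // 2, samples.n_draws - 1]:
            eta = X @ samples.beta[s] + samples.phi[s]
            mu = table.E * np.exp(eta)
            direct = stats.poisson.logpmf(table.Y.astype(int), mu)
            assert np.allclose(ll[s], direct, atol=1e-10)

    def test_null_risk_surface_intercept_near_zero(self):
        """With Y = round(E) (flat risk), the intercept concentrates near 0."""
        cfg = ScenarioConfig(nrows=10, ncols=10, seed=8, base_rate=0.05)
        graph, table, Z, _ = generate_lattice_study(cfg)
        Y = np.round(table.E).astype(float)
        Y[Y < 0] = 0
        from dataclasses import replace
        from frontiercar.standardize import expected_counts
        table = replace(table, Y=Y, E=expected_counts(Y, table.n),
                        covariates=None)
        spec = ModelSpec(n_burn=500, n_keep=500, thin=1, seed=4)
        s = fit_model(table, graph, Z, spec)
        b0 = s.beta[:, 0]
        assert abs(b0.mean()) < 0.1
        assert np.quantile(b0, 0.025) < 0.0 < np.quantile(b0, 0.975)

    def test_missing_expected_counts_errors(self, small_fit):
        graph, table, Z, *_ = small_fit
        from dataclasses import replace
        with pytest.raises(ValueError, match="expected counts"):
            fit_model(replace(table, E=None), graph, Z, ModelSpec(n_burn=10,
                                                                  n_keep=10))

    def test_rank_deficient_design_errors(self, small_fit):
        graph, table, Z, *_ = small_fit
        from dataclasses import replace
        cov = table.covariates.copy()
        cov["dup"] = cov["x1"]
        with pytest.raises(ValueError, match="rank"):
            fit_model(replace(table, covariates=cov), graph, Z,
                      ModelSpec(covariates=("x1", "dup"), n_burn=10, n_keep=10))
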