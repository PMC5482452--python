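import numpy as np
import pytest
from scipy.special import expit, log_expit

import spatocc as sp
from spatocc.grid import SiteDataset
from spatocc.mcmc import (
    MCMCConfig,
    ModelError,
    ModelSpec,
    PosteriorSamples,
    ecological_design,
)
from spatocc.synthetic import TrafficDataset


def make_posterior(beta, rho, gamma=None, z=None, vrho=None, spec=None,
                   x_names=("intercept",), w_names=None):
    beta = np.atleast_2d(np.asarray(beta, float))
    rho = np.atleast_2d(np.asarray(rho, float))
    n_draws = beta.shape[0]
    return PosteriorSamples(
        beta_draws=beta,
        gamma_draws=None if gamma is None else np.atleast_2d(np.asarray(gamma, float)),
        rho_draws=rho,
        vrho_draws=np.full(n_draws, 1.0) if vrho is None else np.asarray(vrho, float),
        z_draws=None if z is None else np.atleast_2d(np.asarray(z)),
        acceptance_rates={},
        mcmc_config=MCMCConfig(n_iter=2, burn_in=1, thin=1, n_chains=1),
        spec=spec or ModelSpec(),
        x_names=x_names,
        w_names=w_names,
    )


class TestModelSpec:
    def test_bad_prior_variance(self):
        with pytest.raises(ModelError):
            ModelSpec(prior_coef_variance=0.0)

    def test_bad_vrho_bounds(self):
        with pytest.raises(ModelError):
            ModelSpec(prior_vrho_bounds=(5.0, 1.0))

    def test_interaction_requires_mains(self):
        with pytest.raises(ModelError):
            ModelSpec(ecological_terms=("a",), interactions=(("a", "b"),))

    def test_interaction_design_restandardized(self, sim_dataset):
        data, _ = sim_dataset
        spec = ModelSpec(ecological_terms=("cov1", "cov2"),
                         interactions=(("cov1", "cov2"),))
        X, names = ecological_design(data, spec)
        assert names == ("intercept", "cov1", "cov2", "cov1:cov2")
        assert abs(X[:, 3].mean()) < 1e-9
        assert abs(X[:, 3].std(ddof=0) - 1) < 1e-9


@pytest.fixture(scope="module")
def fitted():
    g = sp.build_grid((0, 0, 40, 40), 4)
    data, truth = sp.simulate_occupancy_dataset(
        g, beta=[-0.3, 1.0], gamma=[0.8, -0.3], V_rho=0.4,
        visits_per_cell=3, seed=10, detection_terms=("sea_state",),
    )
    spec = ModelSpec(ecological_terms=("cov1",), detection_terms=("sea_state",))
    cfg = MCMCConfig(n_iter=1500, burn_in=700, thin=2, n_chains=2, seed=5)
    post = sp.fit_site_occupancy_icar(data, spec, cfg)
    return data, truth, post, spec, cfg


class TestOccupancyFit:

    def test_detected_cells_always_occupied(self, fitted):
        data, _, post, _, _ = fitted
        detected = data.any_detection().astype(bool)
        assert np.all(post.z_draws[:, detected] == 1)

    def test_rho_sums_to_zero_every_draw(self, fitted):
        _, _, post, _, _ = fitted
        assert np.max(np.abs(post.rho_draws.sum(axis=1))) < 1e-6

    def test_vrho_within_prior_bounds(self, fitted):
        _, _, post, spec, _ = fitted
        a, b = spec.prior_vrho_bounds
        assert np.all((post.vrho_draws > a) & (post.vrho_draws < b))

    def test_chain_determinism(self, fitted):
        data, _, post, spec, cfg = fitted
        again = sp.fit_site_occupancy_icar(data, spec, cfg)
        np.testing.assert_array_equal(post.beta_draws, again.beta_draws)
        np.testing.assert_array_equal(post.rho_draws, again.rho_draws)
        np.testing.assert_array_equal(post.vrho_draws, again.vrho_draws)

    def test_acceptance_rates_reported(self, fitted):
        _, _, post, _, _ = fitted
        for block in ("beta", "gamma", "rho", "vrho"):
            assert 0.05 < post.acceptance_rates[block] < 0.95

    def test_no_visits_error(self, grid3x3):
        data = SiteDataset(
            grid=grid3x3, X=np.ones((9, 1)), x_names=("intercept",),
            W=np.ones((0, 1)), w_names=("intercept",),
            y=np.empty(0, int), visit_cell=np.empty(0, int), visits=np.zeros(9, int),
        )
        with pytest.raises(ModelError, match="no visits"):
            sp.fit_site_occupancy_icar(data, ModelSpec())

    def test_all_detected_degenerate_error(self, grid3x3):
        data = SiteDataset(
            grid=grid3x3, X=np.ones((9, 1)), x_names=("intercept",),
            W=np.ones((9, 1)), w_names=("intercept",),
            y=np.ones(9, int), visit_cell=np.arange(9), visits=np.ones(9, int),
        )
        with pytest.raises(ModelError, match="degenerate"):
            sp.fit_site_occupancy_icar(data, ModelSpec())

    def test_unknown_term_error(self, sim_dataset):
        data, _ = sim_dataset
        with pytest.raises(Exception, match="unknown"):
            sp.fit_site_occupancy_icar(
                data, ModelSpec(ecological_terms=("nope",)),
                MCMCConfig(n_iter=20, burn_in=10, thin=1, n_chains=1),
            )

    def test_quadrature_oracle_intercept_only(self):
        # 12-cell dataset, no spatial effect, detection fixed at 0.5:
        # posterior mean occupancy probability vs 1-D quadrature over the
        # ecological intercept
        g = sp.build_grid((0, 0, 16, 12), 4)
        rng = np.random.default_rng(3)
        z = np.array([1, 1, 0, 1, 0, 0, 1, 0, 1, 0, 0, 1])
        n_vis = 3
        vc = np.repeat(np.arange(12), n_vis)
        y = ((rng.random(36) < 0.5) & (z[vc] == 1)).astype(int)
        data = SiteDataset(
            grid=g, X=np.ones((12, 1)), x_names=("intercept",),
            W=np.ones((36, 1)), w_names=("intercept",),
            y=y, visit_cell=vc, visits=np.full(12, n_vis),
        )
        # quadrature with z marginalized out, delta = 0.5 known
        b_grid = np.linspace(-40, 40, 4001)
        detected = data.any_detection().astype(bool)
        k = np.bincount(vc, weights=y, minlength=12)
        loglik = np.zeros_like(b_grid)
        for i in range(12):
            pi = expit(b_grid)
            per_visit = 0.5**n_vis  # delta^k (1-delta)^(n-k) at delta=.5
            if detected[i]:
                loglik += np.log(pi * per_visit)
            else:
                loglik += np.log(pi * per_visit + (1 - pi))
        logpost = loglik - b_grid**2 / (2 * 100.0)
        w = np.exp(logpost - logpost.max())
        expected_occ = float((w * expit(b_grid)).sum() / w.sum())

        spec = ModelSpec(detection_terms=(), prior_vrho_bounds=(0.0, 1e-6))
        post = sp.fit_site_occupancy_icar(
            data, spec,
            MCMCConfig(n_iter=24000, burn_in=4000, thin=2, n_chains=2, seed=11),
            fixed_gamma=np.array([0.0]),
        )
        mcmc_occ = float(expit(post.beta_draws[:, 0] + 0.0).mean())
        assert mcmc_occ == pytest.approx(expected_occ, abs=0.02)


class TestBinomialFit:
    def test_successes_exceed_trials_error(self, grid3x3):
        with pytest.raises(Exception):
            TrafficDataset(
                grid=grid3x3, X=np.ones((9, 1)), x_names=("intercept",),
                trials=np.ones(9, int), successes=np.full(9, 2),
            )

    def test_all_successes_pushes_pi_up(self, grid5x5):
        data = TrafficDataset(
            grid=grid5x5, X=np.ones((25, 1)), x_names=("intercept",),
            trials=np.full(25, 2), successes=np.full(25, 2),
        )
        post = sp.fit_binomial_icar(
            data, ModelSpec(),
            MCMCConfig(n_iter=1500, burn_in=500, thin=2, n_chains=1, seed=3),
        )
        X, _ = ecological_design(data, post.spec)
        surf = sp.predict_surface(post, X)
        assert np.all(surf.prob_median >= 0.5)

    def test_glm_reduction_oracle(self):
        # V_rho prior collapsed to ~0 at n=400: beta vs Bernoulli-GLM MLE
        import statsmodels.api as sm

        g = sp.build_grid((0, 0, 80, 80), 4)
        data, _ = sp.simulate_traffic_dataset(g, beta=[-0.2, 0.9], seed=21)
        spec = ModelSpec(ecological_terms=("dist_coast",), prior_vrho_bounds=(0.0, 1e-6))
        post = sp.fit_binomial_icar(
            data, spec, MCMCConfig(n_iter=4000, burn_in=1500, thin=2, n_chains=1, seed=4)
        )
        X, _ = ecological_design(data, spec)
        mle = sm.GLM(data.successes, X, family=sm.families.Binomial()).fit().params
        post_mean = post.beta_draws.mean(axis=0)
        post_sd = post.beta_draws.std(axis=0, ddof=1)
        assert np.all(np.abs(post_mean - mle) < 2 * post_sd)

    def test_rejects_detection_terms(self, grid3x3):
        data = TrafficDataset(
            grid=grid3x3, X=np.ones((9, 1)), x_names=("intercept",),
            trials=np.ones(9, int), successes=np.zeros(9, int),
        )
        with pytest.raises(ModelError):
            sp.fit_binomial_icar(data, ModelSpec(detection_terms=("effort",)))

    def test_distance_effect_detected_in_most_seeds(self):
        # scaled power check: the 95% CI for the distance coefficient
        # excludes 0 in nearly all replicates at this effect size
        g = sp.build_grid((0, 0, 100, 80), 4)  # 500 cells
        spec = ModelSpec(ecological_terms=("dist_coast",), prior_vrho_bounds=(0.0, 1.0))
        hits = 0
        n_seeds = 10
        for seed in range(n_seeds):
            data, _ = sp.simulate_traffic_dataset(g, beta=[0.0, 1.0], V_rho=0.2, seed=seed)
            post = sp.fit_binomial_icar(
                data, spec,
                MCMCConfig(n_iter=1200, burn_in=600, thin=2, n_chains=1, seed=seed),
            )
            lo, hi = np.quantile(post.beta_draws[:, 1], [0.025, 0.975])
            hits += int(lo > 0)
        assert hits >= n_seeds - 1


class TestPredictSurface:
    def test_zero_draws_give_half(self):
        post = make_posterior(beta=np.zeros((5, 1)), rho=np.zeros((5, 4)))
        surf = sp.predict_surface(post, np.ones((4, 1)))
        np.testing.assert_allclose(surf.prob_median, 0.5)

    def test_single_draw_is_exact(self):
        post = make_posterior(beta=[[0.7]], rho=[[0.1, -0.1]])
        surf = sp.predict_surface(post, np.ones((2, 1)))
        np.testing.assert_allclose(surf.prob_median, expit(np.array([0.8, 0.6])))

    def test_monotone_in_positive_coefficient(self):
        rng = np.random.default_rng(0)
        beta = np.column_stack([rng.normal(0, 1, 50), rng.uniform(0.5, 1.5, 50)])
        post = make_posterior(beta=beta, rho=np.zeros((50, 3)),
                              x_names=("intercept", "cov"))
        X_lo = np.array([[1.0, 0.0], [1.0, 0.0], [1.0, 0.0]])
        X_hi = np.array([[1.0, 1.0], [1.0, 1.0], [1.0, 1.0]])
        lo = sp.predict_surface(post, X_lo, use_rho=False)
        hi = sp.predict_surface(post, X_hi, use_rho=False)
        assert np.all(hi.prob_median > lo.prob_median)

    def test_column_mismatch_error(self):
        post = make_posterior(beta=[[0.0]], rho=[[0.0, 0.0]])
        with pytest.raises(ModelError):
            sp.predict_surface(post, np.ones((2, 3)))

    def test_new_cells_use_zero_rho(self):
        post = make_posterior(beta=[[0.0]], rho=[[2.0, -2.0]])
        surf = sp.predict_surface(post, np.ones((5, 1)))  # 5 != 2 fitted cells
        assert not surf.rho_included
        np.testing.assert_allclose(surf.prob_median, 0.5)


def _toy_occupancy_data(grid):
    # cell 0: two detections over two visits; cell 1: two misses; rest unvisited
    n = grid.n_cells
    return SiteDataset(
        grid=grid, X=np.ones((n, 1)), x_names=("intercept",),
        W=np.ones((4, 1)), w_names=("intercept",),
        y=np.array([1, 1, 0, 0]), visit_cell=np.array([0, 0, 1, 1]),
        visits=np.r_[2, 2, np.zeros(n - 2, int)],
    )


class TestDIC:
    def test_degenerate_posterior_zero_complexity(self, grid3x3):
        data = _toy_occupancy_data(grid3x3)
        beta = np.tile([0.3], (10, 1))
        gamma = np.tile([0.2], (10, 1))
        rho = np.zeros((10, 9))
        post = make_posterior(beta, rho, gamma=gamma,
                              spec=ModelSpec(detection_terms=()),
                              w_names=("intercept",))
        dic, dbar, pd_eff = sp.compute_dic(post, data)
        assert pd_eff == pytest.approx(0.0, abs=1e-9)
        assert dic == pytest.approx(dbar)

    def test_saturated_perfect_fit_deviance_zero(self, grid3x3):
        data = _toy_occupancy_data(grid3x3)
        rho = np.zeros((1, 9))
        rho[0, 0] = 40.0   # pi -> 1 at the detected cell
        rho[0, 1] = -40.0  # pi -> 0 at the undetected cell
        post = make_posterior([[0.0]], rho, gamma=[[40.0]],  # delta -> 1
                              spec=ModelSpec(detection_terms=()),
                              w_names=("intercept",))
        dic, dbar, pd_eff = sp.compute_dic(post, data)
        assert dbar == pytest.approx(0.0, abs=1e-6)

    def test_empty_posterior_error(self, grid3x3):
        data = _toy_occupancy_data(grid3x3)
        post = make_posterior(np.zeros((0, 1)), np.zeros((0, 9)),
                              gamma=np.zeros((0, 1)),
                              spec=ModelSpec(detection_terms=()),
                              w_names=("intercept",))
        with pytest.raises(ModelError):
            sp.compute_dic(post, data)

    def test_binomial_dic_matches_manual_deviance(self, grid3x3):
        data = TrafficDataset(
            grid=grid3x3, X=np.ones((9, 1)), x_names=("intercept",),
            trials=np.full(9, 3), successes=np.array([0, 1, 2, 3, 1, 2, 0, 3, 1]),
        )
        beta = np.array([[0.4], [0.1], [-0.2]])
        post = make_posterior(beta, np.zeros((3, 9)), spec=ModelSpec())
        dic, dbar, pd_eff = sp.compute_dic(post, data)
        s = data.successes
        f = data.trials - s

        def dev(b):
            eta = np.full(9, b)
            return -2 * float(s @ log_expit(eta) + f @ log_expit(-eta))

        expected_dbar = np.mean([dev(b) for b in beta[:, 0]])
        assert dbar == pytest.approx(expected_dbar, abs=1e-9)
        assert pd_eff == pytest.approx(expected_dbar - dev(0.1), abs=1e-9)

    def test_cell_permutation_equivariance(self, grid3x3):
        # deterministic pieces are invariant under cell relabeling
        data = _toy_occupancy_data(grid3x3)
        rng = np.random.default_rng(8)
        beta = rng.normal(0, 0.5, (6, 1))
        gamma = rng.normal(0, 0.5, (6, 1))
        rho = rng.normal(0, 0.5, (6, 9))
        rho -= rho.mean(axis=1, keepdims=True)
        post = make_posterior(beta, rho, gamma=gamma,
                              spec=ModelSpec(detection_terms=()),
                              w_names=("intercept",))
        dic1 = sp.compute_dic(post, data)

        perm = rng.permutation(9)
        inv = np.argsort(perm)
        data_p = SiteDataset(
            grid=data.grid, X=data.X[perm], x_names=data.x_names,
            W=data.W, w_names=data.w_names, y=data.y,
            visit_cell=inv[data.visit_cell], visits=data.visits[perm],
        )
        post_p = make_posterior(beta, rho[:, perm], gamma=gamma,
                                spec=ModelSpec(detection_terms=()),
                                w_names=("intercept",))
        dic2 = sp.compute_dic(post_p, data_p)
        assert dic1 == pytest.approx(dic2, abs=1e-9)
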