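import numpy as np
import pytest
from scipy import stats

from island_discovery import (
    DiscoveryCountModel, DistanceMatrix, ModelData, ModelSpec,
    ParameterVector, build_count_panel, exclude_single_island_endemics,
    fit_all_models, gp_covariance, log_likelihood, log_prior,
)


def _toy_distance(n=3, scale=1.0):
    rng = np.random.default_rng(7)
    pts = rng.random((n, 2)) * scale
    d = np.sqrt(((pts[:, None] - pts[None, :]) ** 2).sum(-1))
    return DistanceMatrix(islands=[f"I{i}" for i in range(n)], d=d)


def _toy_data(n=3, harbor=True, seed=5):
    rng = np.random.default_rng(seed)
    D = _toy_distance(n)
    return ModelData(s=rng.poisson(5, n), x=stats.zscore(rng.random(n), ddof=1),
                     h=(np.arange(n) < 1).astype(float) if harbor else None,
                     D=D)


class TestGPCovariance:
    def test_constant_kernel_at_zero_decay(self):
        D = _toy_distance(3)
        G = gp_covariance(1.0, 0.0, D)
        off = G[~np.eye(3, dtype=bool)]
        assert np.allclose(off, 1.0)
        assert np.allclose(np.diag(G), 1.01)

    def test_closed_form_off_diagonal(self):
        d = np.array([[0.0, 1.0], [1.0, 0.0]])
        G = gp_covariance(2.0, 0.5, d)
        assert G[0, 1] == pytest.approx(2.0 * np.exp(-0.5), abs=1e-12)
        assert G[0, 1] == pytest.approx(1.2131, abs=1e-4)

    def test_kernel_decays_to_zero(self):
        d = np.array([[0.0, 1e6], [1e6, 0.0]])
        G = gp_covariance(1.0, 1.0, d)
        assert G[0, 1] == 0.0

    def test_invalid_inputs(self):
        D = _toy_distance(2)
        with pytest.raises(ValueError, match="eta2"):
            gp_covariance(-1.0, 1.0, D)
        with pytest.raises(ValueError, match="symmetric"):
            gp_covariance(1.0, 1.0, np.array([[0.0, 1.0], [2.0, 0.0]]))

    def test_positive_definite_for_random_hyperparameters(self, rng):
        D = _toy_distance(9, scale=2.0)
        for _ in range(100):
            eta2 = rng.gamma(1.0, 2.0) + 1e-6
            rho2 = rng.gamma(1.0, 2.0)
            np.linalg.cholesky(gp_covariance(eta2, rho2, D))  # must not raise


class TestLogLikelihood:
    def test_zero_count_unit_rate(self):
        data = ModelData(s=[0], x=[0.0], h=None,
                         D=DistanceMatrix(islands=["A"], d=np.zeros((1, 1))))
        params = ParameterVector(0.0, 0.0, None, 1.0, 1.0, np.zeros(1))
        # s, x need len >= 1; lambda = exp(0) = 1, logpmf(0) = -1
        assert log_likelihood(data, params)[0] == pytest.approx(-1.0)

    def test_two_counts_unit_rate(self):
        data = ModelData(s=[2], x=[0.0], h=None,
                         D=DistanceMatrix(islands=["A"], d=np.zeros((1, 1))))
        params = ParameterVector(0.0, 0.0, None, 1.0, 1.0, np.zeros(1))
        assert log_likelihood(data, params)[0] == pytest.approx(
            -1.0 - np.log(2.0))

    def test_psi_cancelling_predictor_reproduces_unit_rate(self):
        data = _toy_data(harbor=False)
        params = ParameterVector(1.3, -0.4, None, 1.0, 1.0,
                                 -(1.3 - 0.4 * data.x))
        expected = stats.poisson.logpmf(data.s, 1.0)
        assert log_likelihood(data, params) == pytest.approx(expected)

    def test_matches_scipy_poisson(self, rng):
        data = _toy_data(n=5)
        params = ParameterVector(0.5, 0.2, 0.3, 1.0, 1.0,
                                 rng.normal(0, 0.5, 5))
        lam = np.exp(0.5 + 0.2 * data.x + 0.3 * data.h + params.psi)
        assert log_likelihood(data, params) == pytest.approx(
            stats.poisson.logpmf(data.s, lam), abs=1e-12)


class TestLogPrior:
    def test_matches_independent_scipy_evaluation(self, rng):
        D = _toy_distance(4)
        for _ in range(50):
            params = ParameterVector(
                gamma0=rng.normal(0, 3), gamma_cov=rng.normal(0, 3),
                gamma_harbor=rng.normal(0, 3),
                eta2=rng.gamma(1, 1) + 1e-3, rho2=rng.gamma(1, 1) + 1e-3,
                psi=rng.normal(0, 1, 4))
            expected = (
                stats.norm.logpdf([params.gamma0, params.gamma_cov,
                                   params.gamma_harbor], 0, 10).sum()
                + stats.halfcauchy.logpdf([params.eta2, params.rho2]).sum()
                + stats.multivariate_normal.logpdf(
                    params.psi, np.zeros(4),
                    gp_covariance(params.eta2, params.rho2, D)))
            assert log_prior(params, D) == pytest.approx(expected, abs=1e-10)

    def test_parameter_vector_rejects_nonpositive_variance(self):
        with pytest.raises(ValueError, match="eta2"):
            ParameterVector(0.0, 0.0, None, -1.0, 1.0, np.zeros(2))


class TestModelSpec:
    @pytest.mark.parametrize("covariate,harbor,acronym", [
        ("tri", True, "tri.h"), ("age", False, "ag"), ("altitude", True,
                                                       "al.h"),
        ("area", False, "ar"), ("age", True, "ag.h"),
    ])
    def test_acronyms(self, covariate, harbor, acronym):
        assert ModelSpec(covariate, include_harbor=harbor).acronym == acronym

    def test_unknown_covariate(self):
        with pytest.raises(ValueError, match="covariate"):
            ModelSpec("rainfall")


class TestLogPosteriorConsistency:
    def test_transformed_posterior_equals_direct_evaluation(self, rng):
        """Sampler-internal log posterior = sum loglik + log prior + Jacobian,
        cross-checked against an independent scipy evaluation."""
        data = _toy_data(n=5)
        model = DiscoveryCountModel(data, ModelSpec("tri", include_harbor=True))
        for _ in range(100):
            theta = np.concatenate([
                rng.normal(0, 2, 3), rng.normal(0, 1, 2),
                rng.normal(0, 1, 5)])
            params = model._unpack(theta)
            L = model._chol(theta[3], theta[4])
            direct = (log_likelihood(data, params).sum()
                      + log_prior(params, data.D)
                      + theta[3] + theta[4])  # log-Jacobian of exp transform
            assert model._log_posterior(theta, L) == pytest.approx(
                direct, abs=1e-10)


class TestSampler:
    def test_same_seed_identical_draws(self, islands4, records10):
        modelled = exclude_single_island_endemics(records10)
        panel = build_count_panel(modelled, islands4, [1900])
        model = DiscoveryCountModel.from_panel(panel, islands4, 1900)
        a = model.fit(n_draws=100, n_chains=2, seed=11)
        b = model.fit(n_draws=100, n_chains=2, seed=11)
        assert np.array_equal(a._theta, b._theta)

    def test_acceptance_rates_in_healthy_range(self, islands4, records10):
        modelled = exclude_single_island_endemics(records10)
        panel = build_count_panel(modelled, islands4, [1975])
        model = DiscoveryCountModel.from_panel(panel, islands4, 1975,
                                               include_harbor=True)
        res = model.fit(n_draws=1000, n_chains=2, seed=4)
        rates = np.asarray(res.accept_rates)
        assert ((rates >= 0.1) & (rates <= 0.6)).all()

    def test_single_chain_rejected(self, islands4, records10):
        panel = build_count_panel(records10, islands4, [1900])
        model = DiscoveryCountModel.from_panel(panel, islands4, 1900)
        with pytest.raises(ValueError, match="chains"):
            model.fit(n_draws=10, n_chains=1)

    def test_harbor_spec_requires_indicator(self):
        data = _toy_data(harbor=False)
        with pytest.raises(ValueError, match="harbor"):
            DiscoveryCountModel(data, ModelSpec("tri", include_harbor=True))

    def test_effect_sign_recovered_under_informative_data(self):
        """Steep covariate effect with large counts: the posterior mean of
        the slope has the true sign in nearly all replicate fits."""
        from island_discovery import SyntheticConfig, generate_archipelago, \
            generate_counts

        hits = 0
        n_rep = 20
        for rep in range(n_rep):
            cfg = SyntheticConfig(seed=1000 + rep, gamma0=3.5, gamma_cov=0.8,
                                  gamma_harbor=0.0, eta2=0.05, rho2=1.0)
            islands = generate_archipelago(cfg)
            panel, truth = generate_counts(islands, cfg)
            model = DiscoveryCountModel.from_panel(panel, islands, 1975,
                                                   covariate="tri")
            res = model.fit(n_draws=500, n_chains=2, seed=rep)
            if res.draws("gamma_cov").mean() > 0:
                hits += 1
        assert hits >= int(0.95 * n_rep)


class TestModelGrid:
    def test_single_period_grid_has_eight_models(self, islands4, records10):
        modelled = exclude_single_island_endemics(records10)
        panel = build_count_panel(modelled, islands4, [1900])
        fits = fit_all_models(panel, islands4, n_draws=100, n_chains=2,
                              seed=1)
        assert len(fits) == 8
        acronyms = {a for (_, a) in fits}
        assert acronyms == {"ag", "ag.h", "al", "al.h", "ar", "ar.h",
                            "tri", "tri.h"}

    def test_six_periods_give_48_models(self, islands4, records10):
        modelled = exclude_single_island_endemics(records10)
        panel = build_count_panel(modelled, islands4)
        fits = fit_all_models(panel, islands4, n_draws=20, n_chains=2, seed=1)
        assert len(fits) == 48
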