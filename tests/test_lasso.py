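"""Bayesian lasso: standardization, Gibbs sampler, shrinkage selection,
convergence diagnostics."""

import numpy as np
import pytest
from scipy import stats

from invadescape.errors import ConfigurationError, DimensionError
from invadescape.lasso import (LassoDesign, LassoPosterior, MCMCConfig,
                               MCMC_PRESETS, build_design, default_tau_grid,
                               fit_lasso, gelman_rubin,
                               oos_log_predictive_density, select_tau,
                               standardize)

QUICK = MCMC_PRESETS["smoke"]


def _sparse_design(seed=0, n=300, p=20, k=3, noise=0.1):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, p))
    beta = np.zeros(p)
    beta[:k] = [1.0, -1.0, 1.0][:k]
    y = X @ beta + rng.normal(0, noise, n)
    return build_design(X, y, 0.15, seed=seed), beta


class TestStandardize:
    def test_basic_column(self):
        Z, _, _ = standardize(np.array([[1.0], [2.0], [3.0]]))
        assert Z.mean() == pytest.approx(0.0)
        assert Z.std() == pytest.approx(1.0)

    def test_round_trip(self):
        rng = np.random.default_rng(1)
        X = rng.normal(3, 7, size=(20, 4))
        Z, _, moments = standardize(X)
        np.testing.assert_allclose(moments.inverse_transform(Z), X,
                                   atol=1e-12)

    def test_constant_column_dropped_and_logged(self):
        X = np.column_stack([np.arange(5.0), np.full(5, 2.0),
                             np.arange(5.0) ** 2])
        with pytest.warns(UserWarning, match="constant"):
            Z, _, moments = standardize(X)
        assert Z.shape[1] == 2
        assert list(moments.dropped) == [1]

    def test_all_constant_rejected(self):
        with pytest.raises(ConfigurationError):
            standardize(np.ones((5, 3)))

    def test_validation_uses_training_moments(self):
        X_tr = np.array([[0.0], [2.0]])
        X_val = np.array([[1.0]])
        _, Z_val, _ = standardize(X_tr, X_val)
        assert Z_val[0, 0] == pytest.approx(0.0)  # midpoint of training


class TestGelmanRubin:
    def test_identical_chains_are_converged(self):
        draws = np.random.default_rng(0).normal(size=5000)
        r = gelman_rubin(np.stack([draws, draws, draws]))
        assert r == pytest.approx(1.0, abs=1e-3)

    def test_separated_chains_flagged(self):
        rng = np.random.default_rng(1)
        chains = np.stack([rng.normal(0, 1, 500), rng.normal(10, 1, 500)])
        assert gelman_rubin(chains) > 1.1

    def test_stationary_chains_near_one(self):
        rng = np.random.default_rng(2)
        ok = 0
        for _ in range(20):
            chains = rng.normal(size=(3, 2000))
            ok += gelman_rubin(chains) < 1.05
        assert ok >= 19

    def test_single_chain_rejected(self):
        with pytest.raises(ConfigurationError):
            gelman_rubin(np.zeros((1, 100)))


class TestPredictiveScore:
    def _one_draw_posterior(self, beta0, beta, sigma):
        p = len(beta)
        return LassoPosterior(
            tau=1.0,
            beta0=np.full((1, 1), beta0),
            beta=np.asarray(beta, dtype=float).reshape(1, 1, p),
            sigma=np.full((1, 1), sigma),
            rhat=np.ones(p + 2), converged=True,
        )

    def test_degenerate_posterior_matches_closed_form(self):
        post = self._one_draw_posterior(0.5, [1.0, -2.0], 1.3)
        Z_val = np.array([[0.2, 0.4], [-1.0, 0.3]])
        y_val = np.array([0.0, 1.0])
        mu = 0.5 + Z_val @ np.array([1.0, -2.0])
        expected = stats.norm.logpdf(y_val, mu, 1.3).sum()
        score = oos_log_predictive_density(post, Z_val, y_val)
        assert score == pytest.approx(expected, abs=1e-12)

    def test_point_at_prediction_with_unit_sigma(self):
        post = self._one_draw_posterior(0.0, [0.0], 1.0)
        score = oos_log_predictive_density(post, np.array([[0.0]]),
                                           np.array([0.0]))
        assert score == pytest.approx(np.log(1 / np.sqrt(2 * np.pi)))

    def test_score_decreases_for_shifted_validation(self):
        design, _ = _sparse_design()
        post = fit_lasso(design, 5.0, QUICK, seed=0)
        near = oos_log_predictive_density(post, design.Z_val, design.y_val)
        far = oos_log_predictive_density(post, design.Z_val,
                                         design.y_val + 50.0)
        assert far < near

    def test_empty_validation_rejected(self):
        post = self._one_draw_posterior(0.0, [0.0], 1.0)
        with pytest.raises(DimensionError):
            oos_log_predictive_density(post, np.zeros((0, 1)), np.zeros(0))


class TestFitLasso:
    def test_huge_tau_shrinks_everything(self):
        design, _ = _sparse_design()
        post = fit_lasso(design, 1e6, QUICK, seed=1)
        assert np.abs(post.beta_mean).max() < 0.01 * design.y_train.std()

    def test_sparse_signal_recovered(self):
        design, beta = _sparse_design(seed=3)
        post = fit_lasso(design, 2.0, MCMC_PRESETS["reduced"], seed=3)
        ci = post.beta_interval()
        nz = np.nonzero(beta)[0]
        # true effects significant, correctly signed, and close to truth
        assert ((ci[nz, 0] > 0) | (ci[nz, 1] < 0)).all()
        assert (np.sign(post.beta_mean[nz]) == np.sign(beta[nz])).all()
        np.testing.assert_allclose(post.beta_mean[nz], beta[nz], atol=0.1)

    def test_map_oracle_sign_agreement(self):
        """Posterior means agree in sign with a coordinate-descent lasso MAP
        at the matched penalty for all non-negligible coefficients."""
        from sklearn.linear_model import Lasso

        design, _ = _sparse_design(seed=4)
        tau = 5.0
        post = fit_lasso(design, tau, MCMC_PRESETS["reduced"], seed=4)
        sigma2 = post.sigma_mean**2
        alpha = tau * sigma2 / design.n_train
        mapfit = Lasso(alpha=alpha, fit_intercept=True)
        mapfit.fit(design.Z_train, design.y_train)
        big = np.abs(post.beta_mean) > 0.05
        assert (np.sign(post.beta_mean[big])
                == np.sign(mapfit.coef_[big])).all()

    def test_shrinkage_monotone_in_tau(self):
        design, _ = _sparse_design(seed=5, noise=0.5)
        totals = []
        for tau in (0.1, 2.0, 50.0, 1000.0):
            post = fit_lasso(design, tau, QUICK, seed=5)
            totals.append(np.abs(post.beta_mean).sum())
        totals = np.array(totals)
        assert (np.diff(totals) <= 0.05 * totals[:-1] + 1e-6).all()

    def test_standardization_invariance(self):
        """Rescaling a raw metric column leaves its standardized coefficient
        unchanged up to Monte-Carlo error."""
        rng = np.random.default_rng(6)
        X = rng.normal(size=(200, 5))
        y = X[:, 0] + rng.normal(0, 0.2, 200)
        d1 = build_design(X, y, 0.15, seed=6)
        X2 = X.copy()
        X2[:, 0] *= 1000.0
        d2 = build_design(X2, y, 0.15, seed=6)
        p1 = fit_lasso(d1, 1.0, QUICK, seed=6).beta_mean[0]
        p2 = fit_lasso(d2, 1.0, QUICK, seed=6).beta_mean[0]
        assert p1 == pytest.approx(p2, abs=0.05)

    def test_nonpositive_tau_rejected(self):
        design, _ = _sparse_design()
        with pytest.raises(ConfigurationError):
            fit_lasso(design, 0.0, QUICK)

    def test_reference_sampler_agreement_on_toy_problem(self):
        """Gibbs posterior matches an affine-invariant ensemble sampler
        (emcee) run on the identical unnormalized posterior, within 3
        Monte-Carlo standard errors."""
        import emcee

        rng = np.random.default_rng(7)
        n, p = 60, 3
        X = rng.normal(size=(n, p))
        y = X @ np.array([1.0, 0.0, -0.5]) + rng.normal(0, 0.3, n)
        Z, _, _ = standardize(X)
        design = LassoDesign(Z, y, Z[:1], y[:1],
                             moments=None)
        tau = 2.0
        post = fit_lasso(design, tau, MCMCConfig(3, 4000, 2000), seed=7)

        def log_prob(theta):
            b0, b, sig = theta[0], theta[1:1 + p], theta[-1]
            if not (0.001 < sig < 30):
                return -np.inf
            resid = y - b0 - Z @ b
            return (-n * np.log(sig) - 0.5 * resid @ resid / sig**2
                    - tau * np.abs(b).sum() - 0.5 * b0**2 / 100.0)

        nwalkers = 16
        start = np.concatenate([[0.0], np.zeros(p), [1.0]])
        p0 = start + 0.01 * rng.normal(size=(nwalkers, p + 2))
        sampler = emcee.EnsembleSampler(nwalkers, p + 2, log_prob)
        sampler.run_mcmc(p0, 4000, progress=False)
        ref = sampler.get_chain(discard=1500, flat=True)

        for j in range(p):
            ref_draws = ref[:, 1 + j]
            gibbs_draws = post.beta.reshape(-1, p)[:, j]
            se = np.sqrt(ref_draws.var() / 200 + gibbs_draws.var() / 200)
            assert abs(ref_draws.mean() - gibbs_draws.mean()) < 3 * se


class TestSelectTau:
    def test_grid_of_length_one(self):
        design, _ = _sparse_design()
        sel = select_tau(design, np.array([3.0]), QUICK, seed=0)
        assert sel.tau_star == 3.0
        assert len(sel.scores) == 1

    def test_strong_signal_has_interior_maximum(self):
        design, _ = _sparse_design(seed=8, n=400, noise=0.3)
        sel = select_tau(design, default_tau_grid(8), QUICK, seed=8)
        assert sel.boundary == "interior"

    def test_noise_does_not_select_minimal_shrinkage(self):
        """Under a null signal the selected rate avoids the weakest
        shrinkage in most seeded replicates."""
        hits = 0
        for seed in range(5):
            rng = np.random.default_rng(100 + seed)
            X = rng.normal(size=(150, 15))
            y = rng.normal(size=150)
            design = build_design(X, y, 0.15, seed=seed)
            sel = select_tau(design, default_tau_grid(6), QUICK, seed=seed)
            hits += sel.tau_star > sel.taus[0]
        assert hits >= 4

    def test_default_grid_spans_24_rates(self):
        grid = default_tau_grid()
        assert len(grid) == 24
        assert (np.diff(grid) > 0).all()
        assert grid[0] > 0 and grid[-1] == pytest.approx(2000.0)

    def test_invalid_grid_rejected(self):
        design, _ = _sparse_design()
        with pytest.raises(ConfigurationError):
            select_tau(design, np.array([2.0, 1.0]), QUICK)
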