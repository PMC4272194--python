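"""Quasi-Poisson GLM, the MCMC backend, DIC, CPO and residuals."""

import numpy as np
import pytest
from scipy.special import gammaln
from scipy.stats import poisson

import stcar
from stcar.inference import (
    SamplerControl,
    Samples,
    cpo,
    dic,
    fit_bayes,
    fit_glm,
    residuals,
    tau_full_conditional,
)
from stcar.models import ModelSpec, STDataset


def _glm_data(K=30, T=6, beta=(0.2, 0.3), seed=0, overdisperse=1.0):
    rng = np.random.default_rng(seed)
    E = rng.uniform(40, 80, (K, T))
    X = np.ones((K, T, 2))
    X[:, :, 1] = rng.standard_normal((K, T))
    eta = X @ np.asarray(beta)
    mu = E * np.exp(eta)
    if overdisperse > 1:
        shape = mu / (overdisperse - 1)
        mu = rng.gamma(shape, overdisperse - 1)
    Y = rng.poisson(mu)
    return STDataset(Y=Y, E=E, X=X, covariate_names=("intercept", "x1"))


class TestFitGlm:
    def test_recovers_coefficients(self):
        data = _glm_data(K=50, T=8, seed=1)
        fit = fit_glm(data)
        t = fit.posterior.table
        for name, truth in [("beta_intercept", 0.2), ("beta_x1", 0.3)]:
            assert abs(t.loc[name, "mean"] - truth) < 3 * t.loc[name, "sd"]

    def test_equidispersed_data_dispersion_near_one(self):
        data = _glm_data(K=60, T=10, seed=2)
        fit = fit_glm(data)
        assert fit.diagnostics["dispersion"] == pytest.approx(1.0, abs=0.2)

    def test_overdispersed_data_recovers_factor(self):
        data = _glm_data(K=60, T=10, seed=3, overdisperse=4.5)
        fit = fit_glm(data)
        assert fit.diagnostics["dispersion"] == pytest.approx(4.5, rel=0.25)

    def test_residuals_sum_to_zero_with_intercept(self):
        data = _glm_data(seed=4)
        fit = fit_glm(data)
        assert float(fit.residuals.sum()) == pytest.approx(0.0, abs=1e-5)


class TestTauUpdate:
    def test_conjugate_matches_quadrature(self):
        """Gamma(a + r/2, b + q/2) mean agrees with grid integration of the
        unnormalised conditional density prior(tau) * tau^(r/2) exp(-tau q/2)."""
        a, b, r, q = 1.0, 0.0005, 17, 3.4
        shape, rate = tau_full_conditional((a, b), r, q)
        assert shape == a + r / 2 and rate == b + q / 2
        grid = np.linspace(1e-8, 60, 400001)
        logd = (a - 1 + r / 2) * np.log(grid) - grid * (b + q / 2)
        d = np.exp(logd - logd.max())
        mean_quad = np.trapezoid(grid * d, grid) / np.trapezoid(d, grid)
        assert mean_quad == pytest.approx(shape / rate, rel=1e-6)


class TestFitBayes:
    def test_offset_only_intercept_posterior(self):
        rng = np.random.default_rng(0)
        K, T = 20, 5
        E = rng.uniform(30, 60, (K, T))
        Y = rng.poisson(E * np.exp(0.3))
        data = STDataset(Y=Y, E=E, X=np.ones((K, T, 1)), covariate_names=("intercept",))
        fit = fit_bayes(
            ModelSpec(family="glm"), data, control=SamplerControl.fast(1)
        )
        target = np.log(Y.sum() / E.sum())
        row = fit.posterior.table.loc["beta_intercept"]
        assert row["mean"] == pytest.approx(target, abs=3 * max(row["sd"], 1e-3))

    def test_seeded_runs_reproducible(self, small_dataset):
        g, data, _ = small_dataset
        spec = ModelSpec(
            family="bym_nonseparable", adjacency=stcar.build_st_adjacency(g, 3)
        )
        ctrl = SamplerControl(n_chains=1, n_iter=800, n_burn=400, thin=4, seed=9)
        a = fit_bayes(spec, data, control=ctrl)
        b = fit_bayes(spec, data, control=ctrl)
        assert np.array_equal(
            a.posterior.table["mean"].to_numpy(), b.posterior.table["mean"].to_numpy()
        )
        assert a.dic == b.dic

    def test_marginal_intervals_for_every_cell(self, small_dataset):
        g, data, _ = small_dataset
        spec = ModelSpec(
            family="localised_nonseparable",
            adjacency=stcar.build_st_adjacency(g, 3),
        )
        fit = fit_bayes(
            spec, data, control=SamplerControl(1, 1000, 500, 5, seed=2)
        )
        lo, hi = fit.posterior.intervals("phi_tilde")
        n = data.n_obs + 1
        assert lo.shape == hi.shape == (n,)
        assert np.all(lo <= hi) and np.all(np.isfinite(lo))

    def test_beta_recovery_generating_model(self):
        """Posterior mean of the pollution effect lands within 3 posterior sds
        of truth when fitting the model family the data were generated from."""
        g = stcar.make_lattice(5, 5)
        scen = stcar.Scenario(M=0.5, E_interval=(150, 200), separable=False, n_datasets=1)
        hits = 0
        for seed in range(4):
            data, truth = stcar.generate_dataset(scen, g, 4, seed=100 + seed)
            spec = ModelSpec(
                family="bym_nonseparable", adjacency=stcar.build_st_adjacency(g, 4)
            )
            fit = fit_bayes(spec, data, control=SamplerControl.fast(seed))
            row = fit.posterior.table.loc["beta_pm10"]
            if abs(row["mean"] - truth["beta_true"][1]) < 3 * row["sd"]:
                hits += 1
        assert hits >= 3


class TestDicCpo:
    def _samples(self, data, beta, phi, n=1):
        p = beta.size
        return Samples(
            beta=np.tile(beta, (n, 1)),
            taus={},
            phi_eff=np.tile(phi, (n, 1)),
            components={},
            chain_id=np.zeros(n, dtype=int),
        )

    def test_degenerate_chain_zero_pd(self):
        data = _glm_data(K=10, T=3, seed=5)
        beta = np.array([0.1, 0.2])
        phi = np.zeros(30)
        s = self._samples(data, beta, phi, n=150)
        d, pD = dic(s, data)
        assert pD == pytest.approx(0.0, abs=1e-8)
        y, e, x = data.flat()
        eta = np.log(e) + x @ beta
        dev = -2 * float(np.sum(y * eta - np.exp(eta) - gammaln(y + 1)))
        assert d == pytest.approx(dev)

    def test_single_sample_cpo_is_density(self):
        data = _glm_data(K=6, T=2, seed=6)
        beta = np.array([0.05, -0.1])
        s = self._samples(data, beta, np.zeros(12), n=1)
        got = cpo(s, data)
        y, e, x = data.flat()
        mu = e * np.exp(x @ beta)
        want = poisson.pmf(y, mu)
        assert np.allclose(got, want, rtol=1e-10)

    def test_cpo_matches_quadrature_loo_predictive(self):
        """iid Poisson with a conjugate Gamma posterior: the harmonic-mean CPO
        approaches the exact leave-one-out predictive computed by quadrature."""
        rng = np.random.default_rng(7)
        K, T = 8, 2
        lam_true = 5.0
        Y = rng.poisson(lam_true, (K, T))
        E = np.ones((K, T))
        data = STDataset(Y=Y, E=E, X=np.ones((K, T, 1)))
        y = Y.T.ravel()
        n = y.size
        # posterior for rate with Gamma(0.01, 0.01) prior, all data
        a0, b0 = 0.01, 0.01
        cell = 3
        # exact loo predictive of y[cell]: integrate Poisson pmf against the
        # posterior from the REMAINING observations
        a_loo = a0 + y.sum() - y[cell]
        b_loo = b0 + n - 1
        grid = np.linspace(1e-6, 20, 20001)
        from scipy.stats import gamma as gamma_dist

        dens = gamma_dist.pdf(grid, a_loo, scale=1 / b_loo)
        exact = np.trapezoid(poisson.pmf(y[cell], grid) * dens, grid)
        # harmonic-mean estimator from full-posterior samples
        S = 40000
        lam_s = rng.gamma(a0 + y.sum(), 1 / (b0 + n), S)
        samples = Samples(
            beta=np.zeros((S, 1)),
            taus={},
            phi_eff=np.log(lam_s)[:, None] * np.ones((S, n)),
            components={},
            chain_id=np.zeros(S, dtype=int),
        )
        got = cpo(samples, data)[cell]
        assert got == pytest.approx(exact, rel=0.05)

    def test_noise_covariates_raise_pd(self):
        data = _glm_data(K=25, T=5, seed=8)
        rng = np.random.default_rng(9)
        X2 = np.concatenate([data.X, rng.standard_normal((25, 5, 3))], axis=2)
        data2 = STDataset(Y=data.Y, E=data.E, X=X2)
        ctrl = SamplerControl(1, 3000, 1500, 5, seed=3)
        f1 = fit_bayes(ModelSpec(family="glm"), data, control=ctrl)
        f2 = fit_bayes(ModelSpec(family="glm"), data2, control=ctrl)
        assert f2.pD > f1.pD


class TestResiduals:
    def test_zero_for_perfect_fit(self):
        data = _glm_data(K=10, T=4, seed=10)
        fit = fit_glm(data)
        y, e, x = data.flat()
        # force fitted == observed by replacing Y with the fitted mean
        beta_hat = fit.posterior.table["mean"].to_numpy()
        mu = e * np.exp(x @ beta_hat)
        K, T = data.n_areas, data.n_periods
        r = residuals(fit, data)
        assert np.allclose(r, data.Y - mu.reshape(T, K).T)

    def test_zero_counts_give_negative_residuals(self):
        K, T = 5, 2
        data = STDataset(
            Y=np.zeros((K, T), int), E=np.ones((K, T)), X=np.ones((K, T, 1))
        )
        fit = fit_bayes(
            ModelSpec(family="glm"), data, control=SamplerControl(1, 500, 250, 5, seed=1)
        )
        assert (residuals(fit, data) < 0).all()


class TestSweepEngines:
    """The compiled sweep kernel and its pure-Python twin consume identical
    random streams and produce matching chains (up to libm rounding)."""

    def test_engines_agree(self, small_dataset):
        g, data, _ = small_dataset
        spec = ModelSpec(
            family="localised_nonseparable",
            adjacency=stcar.build_st_adjacency(g, 3),
        )
        ctrl = SamplerControl(n_chains=1, n_iter=600, n_burn=300, thin=3, seed=4)
        a = fit_bayes(spec, data, control=ctrl, engine="numba")
        b = fit_bayes(spec, data, control=ctrl, engine="python")
        np.testing.assert_allclose(
            a.posterior.table["mean"].to_numpy(),
            b.posterior.table["mean"].to_numpy(),
            rtol=1e-7,
            atol=1e-9,
        )
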