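import numpy as np
import pandas as pd
import pytest
from scipy import stats

import pbpkgsa as pg
from pbpkgsa.bayes import (
    FitReport,
    McmcConfig,
    McmcTrace,
    fit_report,
    gelman_rubin,
    log_likelihood,
    make_pbpk_predictor,
    metropolis_within_gibbs,
    run_mcmc,
)


class TestLogLikelihood:
    def test_zero_when_residual_and_normalisation_cancel(self):
        # y = yhat and s^2 = 1/(2 pi) makes both terms vanish
        assert log_likelihood([1.0], [1.0], [1.0 / (2 * np.pi)], [0]) == pytest.approx(
            0.0, abs=1e-12
        )

    def test_unit_residual_unit_variance(self):
        expected = -0.5 - 0.5 * np.log(2 * np.pi)
        assert log_likelihood([1.0], [0.0], [1.0], [0]) == pytest.approx(
            expected, abs=1e-12
        )

    def test_additivity_over_points(self):
        y, yhat, s2 = [0.3, -0.7], [0.1, 0.2], [0.5, 2.0]
        total = log_likelihood(y, yhat, s2, [0, 1])
        parts = log_likelihood([y[0]], [yhat[0]], s2, [0]) + log_likelihood(
            [y[1]], [yhat[1]], s2, [1]
        )
        assert total == pytest.approx(parts, abs=1e-12)

    def test_per_type_variances_are_used(self):
        a = log_likelihood([1.0, 1.0], [0.0, 0.0], [1.0, 4.0], [0, 1])
        b = log_likelihood([1.0, 1.0], [0.0, 0.0], [1.0, 4.0], [0, 0])
        assert a != pytest.approx(b)

    def test_nonpositive_variance_rejected(self):
        with pytest.raises(ValueError):
            log_likelihood([1.0], [0.0], [0.0], [0])


class TestSampler:
    def test_conjugate_normal_posterior(self):
        """Normal likelihood with known sigma and normal prior: the sampler
        must recover the closed-form posterior mean and variance."""
        rng = np.random.default_rng(1)
        sigma, mu0, tau0 = 1.0, 0.0, 10.0
        data = rng.normal(2.0, sigma, size=25)
        post_var = 1.0 / (1.0 / tau0**2 + len(data) / sigma**2)
        post_mean = post_var * (mu0 / tau0**2 + data.sum() / sigma**2)

        def lp(x):
            th = x[0]
            return -0.5 * ((th - mu0) / tau0) ** 2 - 0.5 * np.sum(
                (data - th) ** 2
            ) / sigma**2

        samples, _, _ = metropolis_within_gibbs(
            lp, np.array([0.0]), 6000, step0=0.5, seed=2, adapt_until=1000
        )
        kept = samples[1000:, 0]
        # 3 Monte-Carlo standard errors with a conservative ESS estimate
        ess = kept.size / 10
        mcse_mean = np.sqrt(post_var / ess)
        assert kept.mean() == pytest.approx(post_mean, abs=3 * mcse_mean)
        assert kept.var() == pytest.approx(post_var, rel=0.3)

    def test_stationary_distribution_on_discretised_target(self):
        """Long-run histogram of samples from a standard normal target passes
        a chi-square goodness-of-fit check (detailed-balance sanity)."""
        samples, _, _ = metropolis_within_gibbs(
            lambda x: -0.5 * x[0] ** 2, np.array([0.0]), 20000, step0=2.0, seed=3
        )
        x = samples[2000::5, 0]
        edges = np.array([-np.inf, -1.5, -1.0, -0.5, 0.0, 0.5, 1.0, 1.5, np.inf])
        obs, _ = np.histogram(x, bins=edges)
        probs = np.diff(stats.norm.cdf(edges))
        # autocorrelation inflates the chi-square scale; thinned draws and a
        # loose significance level keep the check meaningful but stable
        stat = ((obs - len(x) * probs) ** 2 / (len(x) * probs)).sum()
        assert stat < stats.chi2(len(probs) - 1).ppf(0.9999) * 5

    def test_infinite_start_rejected(self):
        with pytest.raises(ValueError):
            metropolis_within_gibbs(lambda x: -np.inf, np.array([0.0]), 10)


class TestGelmanRubin:
    def test_copied_chains_give_unity(self):
        rng = np.random.default_rng(4)
        chain = rng.normal(size=(1, 500, 2))
        chains = np.concatenate([chain, chain], axis=0)
        assert gelman_rubin(chains) == pytest.approx([1.0, 1.0], abs=2e-3)

    def test_divergent_chains_give_large_psrf(self):
        rng = np.random.default_rng(5)
        a = rng.normal(0.0, 0.01, size=(1, 400, 1))
        b = rng.normal(10.0, 0.01, size=(1, 400, 1))
        psrf = gelman_rubin(np.concatenate([a, b], axis=0))
        assert psrf[0] > 100

    def test_psrf_at_least_unity_up_to_dof_correction(self):
        rng = np.random.default_rng(6)
        chains = rng.normal(size=(4, 300, 3))
        assert (gelman_rubin(chains) >= np.sqrt(299 / 300) - 1e-12).all()

    def test_single_chain_rejected(self):
        with pytest.raises(ValueError):
            gelman_rubin(np.zeros((1, 100, 2)))


@pytest.fixture(scope="module")
def tiny_calibration(prior_table, nominal_params):
    designs = [d for d in pg.default_designs() if d.study_id == "1000mg_a"]
    data = pg.generate_dataset(nominal_params, designs, seed=21)
    predict = make_pbpk_predictor(data, nominal_params)
    cfg = McmcConfig(n_iter=120, n_chains=2, seed=9, thin=4, burn_in=0.5)
    trace = run_mcmc(predict, prior_table, ["CLC_AS", "Tg"], data, cfg)
    return data, predict, cfg, trace


class TestRunMcmc:
    def test_same_seed_identical_traces(self, prior_table, tiny_calibration):
        data, predict, cfg, trace = tiny_calibration
        again = run_mcmc(predict, prior_table, ["CLC_AS", "Tg"], data, cfg)
        assert np.array_equal(trace.params, again.params)
        assert np.array_equal(trace.lnl, again.lnl)

    def test_samples_respect_prior_support(self, prior_table, tiny_calibration):
        *_, trace = tiny_calibration
        for j, name in enumerate(trace.names):
            lo, hi = prior_table[name].support
            vals = trace.params[:, :, j]
            assert vals.min() >= lo and vals.max() <= hi

    def test_trace_export_schema(self, tiny_calibration):
        *_, trace = tiny_calibration
        df = trace.to_frame()
        assert {"iteration", "chain", "CLC_AS", "Tg", "LnData"} <= set(df.columns)
        assert df["chain"].nunique() == 2

    def test_invalid_subset_rejected(self, prior_table, tiny_calibration):
        data, predict, cfg, _ = tiny_calibration
        with pytest.raises(ValueError, match="not in prior table"):
            run_mcmc(predict, prior_table, ["NotAParam"], data, cfg)


class TestFitReport:
    def _fake_trace(self, value=1.0):
        return McmcTrace(
            params=np.full((1, 10, 1), value),
            s2=np.full((1, 10, 1), 0.04),
            lnl=np.zeros((1, 10)),
            names=["scale"],
            config=McmcConfig(),
        )

    def _data(self, conc):
        return pd.DataFrame(
            {
                "study_id": "s1",
                "dose": 1000.0,
                "dose_units": "mg",
                "route": "oral",
                "time_h": np.arange(1.0, len(conc) + 1),
                "compound": "APAP",
                "conc": conc,
                "conc_units": "mg/L",
                "body_mass_kg": 70.0,
            }
        )

    def test_perfect_predictions(self):
        data = self._data(np.array([1.0, 2.0, 4.0, 8.0]))
        predict = lambda params: data["conc"].to_numpy() * params["scale"]
        rep = fit_report(self._fake_trace(1.0), data, predict, n_ppc=20)
        assert rep.residual_median == pytest.approx(0.0, abs=1e-12)
        assert rep.r2_by_study["s1"] == pytest.approx(1.0)

    def test_r2_matches_hand_computation(self):
        obs = np.array([1.0, 2.0, 4.0, 8.0])
        data = self._data(obs)
        pred = np.array([1.2, 1.8, 4.5, 7.0])
        predict = lambda params: pred
        rep = fit_report(self._fake_trace(), data, predict, n_ppc=10)
        lo, lp = np.log10(obs), np.log10(pred)
        expected = 1.0 - ((lo - lp) ** 2).sum() / ((lo - lo.mean()) ** 2).sum()
        assert rep.r2_by_study["s1"] == pytest.approx(expected, abs=1e-12)
        assert rep.residual_median == pytest.approx(np.median(lp - lo), abs=1e-12)

    def test_empty_trace_rejected(self):
        trace = self._fake_trace()
        trace.params = np.empty((0, 0, 0))
        with pytest.raises(ValueError):
            fit_report(trace, self._data(np.ones(3)), lambda p: np.ones(3))

    def test_prediction_interval_coverage_on_self_generated_data(
        self, tiny_calibration
    ):
        data, predict, _, trace = tiny_calibration
        rep = fit_report(trace, data, predict, n_ppc=150, seed=3)
        # nominal 95% interval; binomial error with n=24 points is wide
        assert rep.pi_coverage >= 0.75
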