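"""MCMC engine: priors, diagnostics, determinism, prior recovery, and
posterior recovery of the generating parameters on the study-scale fixture."""

import numpy as np
import pytest
from scipy import stats

import bayescfa as b
from bayescfa.model import CFAParameters, ModelSpec
from bayescfa.sampler import PosteriorDraws, PriorSettings, log_prior


def _draws_from_array(values):
    """Wrap a raw (chains, kept, k) array in a PosteriorDraws for the
    diagnostics, which only touch .values."""
    spec = ModelSpec(("x",), {})
    k = values.shape[2]
    return PosteriorDraws(values=values, param_names=[f"p{i}" for i in range(k)],
                          spec=spec, seed=0, acceptance=np.ones(values.shape[0]))


class TestLogPrior:
    def test_component_densities(self):
        # p=1 independence model: prior = intercept normal + residual-SD gamma
        spec = ModelSpec(("x",), {})
        priors = PriorSettings()

        def lp(nu, sd):
            params = CFAParameters(nu=np.array([nu]), lam=np.zeros((1, 0)),
                                   theta=np.array([sd**2]), factor_sds=np.zeros(0),
                                   factor_corr=np.eye(0))
            return log_prior(params, priors, spec)

        # residual SD = 2 under Gamma(1, 0.5): log(0.5) - 1
        assert lp(0.0, 2.0) - lp(0.0, 1.0) == pytest.approx(
            (np.log(0.5) - 1.0) - (np.log(0.5) - 0.5))
        expected = stats.norm.logpdf(0.0, 0.0, 32.0) + stats.expon.logpdf(2.0, scale=2.0)
        assert lp(0.0, 2.0) == pytest.approx(expected, rel=1e-10)

    def test_loading_density_and_correlation_support(self, gp, specs):
        spec = specs["three_factor"]
        priors = PriorSettings()
        base = CFAParameters(nu=gp.intercepts, lam=gp.lam, theta=gp.residual_variances,
                             factor_sds=np.ones(3), factor_corr=gp.factor_correlations)
        lp0 = log_prior(base, priors, spec)
        assert np.isfinite(lp0)
        # zeroing one free loading changes the prior by the N(0,100) density ratio
        lam2 = gp.lam.copy()
        lam2[1, 0] = 0.0
        from dataclasses import replace
        lp_zero = log_prior(replace(base, lam=lam2), priors, spec)
        assert lp_zero - lp0 == pytest.approx(
            stats.norm.logpdf(0.0, 0, 10) - stats.norm.logpdf(gp.lam[1, 0], 0, 10))
        # out-of-range correlation -> -inf
        bad = gp.factor_correlations.copy()
        bad[0, 1] = bad[1, 0] = 1.5
        assert log_prior(replace(base, factor_corr=bad), priors, spec) == -np.inf
        # non-PD correlation matrix -> -inf
        npd = np.array([[1.0, 0.95, -0.95], [0.95, 1.0, 0.95], [-0.95, 0.95, 1.0]])
        assert log_prior(replace(base, factor_corr=npd), priors, spec) == -np.inf

    def test_negative_sd_support(self, gp, specs):
        from dataclasses import replace
        base = CFAParameters(nu=gp.intercepts, lam=gp.lam, theta=gp.residual_variances,
                             factor_sds=np.ones(3), factor_corr=gp.factor_correlations)
        assert log_prior(replace(base, theta=-base.theta), PriorSettings(),
                         specs["three_factor"]) == -np.inf

    def test_elliptope_normalization_constant(self):
        # the m=3 jointly-uniform correlation prior is normalized by the
        # elliptope volume pi^2/2; cross-check by Monte Carlo
        rng = np.random.default_rng(0)
        abc = rng.uniform(-1, 1, (500_000, 3))
        a, c, d = abc.T
        det = 1 - a * a - c * c - d * d + 2 * a * c * d
        vol = 8.0 * np.mean(det > 0)
        assert vol == pytest.approx(np.pi**2 / 2, abs=0.02)


class TestDiagnostics:
    def test_psrf_stationary_chains(self):
        rng = np.random.default_rng(2)
        values = rng.standard_normal((3, 10_000, 2))
        r = b.psrf(_draws_from_array(values))
        assert np.all(r > 0.99) and np.all(r < 1.01)

    def test_psrf_separated_chains(self):
        rng = np.random.default_rng(3)
        values = rng.standard_normal((2, 500, 1))
        values[1] += 10.0
        assert b.psrf(_draws_from_array(values))[0] > 1.1

    def test_psrf_single_chain_rejected(self):
        values = np.zeros((1, 100, 1))
        with pytest.raises(ValueError, match="2 chains"):
            b.psrf(_draws_from_array(values))

    def test_psrf_constant_parameter_nan(self):
        rng = np.random.default_rng(4)
        values = rng.standard_normal((2, 100, 2))
        values[:, :, 1] = 7.0
        with pytest.warns(UserWarning, match="zero within-chain"):
            r = b.psrf(_draws_from_array(values))
        assert np.isfinite(r[0]) and np.isnan(r[1])

    def test_mcse_iid_draws(self):
        rng = np.random.default_rng(5)
        values = rng.standard_normal((1, 10_000, 1))
        mcse = b.mcse_batch_means(_draws_from_array(values))[0]
        assert mcse == pytest.approx(0.01, rel=0.3)

    def test_mcse_constant_draws_zero(self):
        values = np.full((1, 400, 1), 3.0)
        assert b.mcse_batch_means(_draws_from_array(values))[0] == 0.0

    def test_mcse_too_few_draws(self):
        values = np.zeros((1, 50, 1))
        with pytest.raises(ValueError, match="100"):
            b.mcse_batch_means(_draws_from_array(values))


class TestPriorRecovery:
    @pytest.fixture(scope="class")
    def prior_draws(self, fixture_data, specs):
        _, sm = fixture_data
        return b.run_chains(sm, specs["three_factor"], seed=7,
                            likelihood_weight=0.0, n_warmup=500, n_kept=3000)

    def test_prior_moments(self, prior_draws):
        flat = prior_draws.stacked()
        nu = flat[:, :12]
        lam = flat[:, 12:21]
        resid_sd = np.sqrt(flat[:, 21:33])
        fsd = flat[:, 33:36]
        assert nu.std() == pytest.approx(32.0, rel=0.10)
        assert lam.std() == pytest.approx(10.0, rel=0.10)
        assert resid_sd.mean() == pytest.approx(2.0, rel=0.10)
        assert fsd.mean() == pytest.approx(2.0, rel=0.15)

    def test_prior_correlations_near_uniform(self, prior_draws):
        # marginals of the jointly-uniform-PD prior are close to uniform;
        # KS at thinned, reduced draws
        corr = prior_draws.stacked()[:, 36:39]
        for j in range(3):
            sub = corr[::60, j]
            p = stats.kstest(sub, "uniform", args=(-1, 2)).pvalue
            assert p > 0.005, f"correlation {j} far from uniform (p={p:.2g})"
        assert np.abs(corr.mean()) < 0.05


class TestRunChains:
    def test_seed_determinism(self, fixture_data, specs):
        _, sm = fixture_data
        kw = dict(n_chains=2, n_warmup=100, n_kept=100, n_starts=1)
        d1 = b.run_chains(sm, specs["three_factor"], seed=11, **kw)
        d2 = b.run_chains(sm, specs["three_factor"], seed=11, **kw)
        assert np.array_equal(d1.values, d2.values)
        d3 = b.run_chains(sm, specs["three_factor"], seed=12, **kw)
        assert not np.array_equal(d1.values, d3.values)

    def test_convergence_contract_on_fixture(self, three_factor_fit):
        report = b.convergence_report(three_factor_fit)
        assert report.psrf_ok, f"PSRF >= 1.1: max {np.nanmax(report.psrf)}"
        assert report.mcse_ok, "MCSE >= 5% of posterior SD"
        assert report.passed

    def test_posterior_recovers_generating_values(self, standardized_draws, gp):
        lam, corr = standardized_draws
        np.testing.assert_allclose(lam.mean(axis=0), gp.loadings, atol=0.02)
        triu = np.triu_indices(3, k=1)
        np.testing.assert_allclose(corr.mean(axis=0), gp.factor_correlations[triu], atol=0.02)

    def test_posterior_mean_matches_ml_oracle(self, fixture_data, specs, standardized_draws):
        # vague priors + n=3868: posterior mean ~ ML solution per standardized parameter
        _, sm = fixture_data
        spec = specs["three_factor"]
        ml = b.standardize(b.ml_estimate(sm, spec), spec)
        lam, corr = standardized_draws
        np.testing.assert_allclose(lam.mean(axis=0), ml.lam.sum(axis=1), atol=0.01)
        triu = np.triu_indices(3, k=1)
        np.testing.assert_allclose(corr.mean(axis=0), ml.factor_corr[triu], atol=0.01)

    def test_credible_interval_coverage(self, coverage_runs):
        hits, total = coverage_runs
        coverage = hits / total
        assert 0.85 <= coverage <= 1.0, f"95% CrI coverage {coverage:.3f} out of range"


class TestTraceExport:
    def test_csv_round_trip_and_shape(self, tmp_path, fixture_data, specs):
        import pandas as pd
        _, sm = fixture_data
        d = b.run_chains(sm, specs["three_factor"], seed=21,
                         n_chains=2, n_warmup=50, n_kept=60, n_starts=1)
        path = tmp_path / "trace.csv"
        b.trace_export(d, path)
        back = pd.read_csv(path)
        assert len(back) == 2 * 60
        np.testing.assert_allclose(
            back[d.param_names].to_numpy().reshape(2, 60, -1), d.values, atol=1e-12)
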