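"""Model structures, implied moments, the marginal likelihood and
standardization."""

import numpy as np
import pytest

import bayescfa as b
from bayescfa.model import (
    CFAParameters,
    ModelSpec,
    SampleMoments,
    implied_moments,
    marginal_loglik,
    saturated_loglik,
)


def _one_factor(p=2, lam=(1.0, 1.0), theta=(1.0, 1.0), sd=1.0, nu=None):
    spec = ModelSpec(tuple(f"x{i}" for i in range(p)), {"F": tuple(f"x{i}" for i in range(p))})
    params = CFAParameters(
        nu=np.zeros(p) if nu is None else np.asarray(nu),
        lam=np.array(lam, dtype=float).reshape(p, 1),
        theta=np.array(theta, dtype=float),
        factor_sds=np.array([sd]),
        factor_corr=np.eye(1),
    )
    return spec, params


class TestModelSpec:
    def test_canonical_structures(self, specs):
        assert set(specs) == {"one_factor", "two_factor_so_fr", "two_factor_fa_fr",
                              "two_factor_fa_so", "three_factor"}
        three = specs["three_factor"]
        assert three.p == 12 and three.m == 3
        assert three.reference_items == ("q1", "q5", "q9")
        assert three.n_free_parameters == 39
        assert specs["one_factor"].n_free_parameters == 36
        # every item loads on exactly one factor
        assert np.all(three.pattern.sum(axis=1) == 1)

    def test_cross_loading_rejected(self):
        with pytest.raises(ValueError, match="more than one factor"):
            ModelSpec(("a", "b"), {"F1": ("a", "b"), "F2": ("b",)})

    def test_unassigned_item_rejected(self):
        with pytest.raises(ValueError, match="not assigned"):
            ModelSpec(("a", "b", "c"), {"F": ("a", "b")})

    def test_config_round_trip(self, specs):
        d = specs["three_factor"].to_dict()
        assert ModelSpec.from_dict(d) == specs["three_factor"]


class TestSampleMoments:
    def test_p_star(self, fixture_data):
        _, sm = fixture_data
        assert sm.p == 12 and sm.p_star == 90

    def test_hand_computed_two_point_example(self):
        sm = b.compute_sample_moments(np.array([[0.0, 0.0], [2.0, 2.0]]))
        np.testing.assert_allclose(sm.ybar, [1.0, 1.0])
        np.testing.assert_allclose(sm.S, [[1.0, 1.0], [1.0, 1.0]])  # divisor N

    def test_missing_values_rejected(self):
        with pytest.raises(ValueError, match="complete_cases"):
            b.compute_sample_moments(np.array([[1.0, np.nan], [2.0, 3.0]]))

    def test_constant_column_warns(self):
        with pytest.warns(UserWarning, match="singular"):
            b.compute_sample_moments(np.array([[1.0, 2.0], [1.0, 3.0], [1.0, 4.0]]))


class TestImpliedMoments:
    def test_single_factor_two_items(self):
        spec, params = _one_factor()
        im = implied_moments(params, spec)
        np.testing.assert_allclose(im.sigma_hat, [[2.0, 1.0], [1.0, 2.0]])

    def test_zero_loadings_diagonal(self):
        spec, params = _one_factor(lam=(0.0, 0.0), theta=(1.5, 2.5))
        np.testing.assert_allclose(implied_moments(params, spec).sigma_hat,
                                   np.diag([1.5, 2.5]))

    def test_printed_solution_implied_correlation(self, gp, specs):
        # implied correlation of items 1,2 = product of standardized loadings
        spec = specs["three_factor"]
        params = CFAParameters(nu=gp.intercepts, lam=gp.lam, theta=gp.residual_variances,
                               factor_sds=np.ones(3), factor_corr=gp.factor_correlations)
        im = implied_moments(params, spec)
        d = np.sqrt(np.diag(im.sigma_hat))
        corr12 = im.sigma_hat[0, 1] / (d[0] * d[1])
        assert corr12 == pytest.approx(0.840, abs=0.002)

    def test_matches_generator_population_covariance(self, gp, specs):
        params = CFAParameters(nu=gp.intercepts, lam=gp.lam, theta=gp.residual_variances,
                               factor_sds=np.ones(3), factor_corr=gp.factor_correlations)
        im = implied_moments(params, specs["three_factor"])
        mu, cov = gp.population_moments()
        np.testing.assert_allclose(im.sigma_hat, cov, atol=1e-12)
        np.testing.assert_allclose(im.mu_hat, mu)

    def test_dimension_mismatch(self, specs):
        spec, params = _one_factor()
        with pytest.raises(ValueError):
            implied_moments(params, specs["three_factor"])


class TestMarginalLoglik:
    def test_saturated_univariate_closed_form(self):
        sm = SampleMoments(S=np.array([[2.0]]), ybar=np.array([1.0]), N=50, p=1)
        expected = -0.5 * 50 * (np.log(2 * np.pi) + np.log(2.0) + 1.0)
        assert saturated_loglik(sm) == pytest.approx(expected, rel=1e-12)

    def test_univariate_chisq_hand_value(self):
        # N=100, s^2=1, ybar=mu=0, sigma^2=2 -> 2(L_sat - L) = 100(log2 - 1/2)
        sm = SampleMoments(S=np.array([[1.0]]), ybar=np.array([0.0]), N=100, p=1)
        spec = ModelSpec(("x",), {})
        params = CFAParameters(nu=np.array([0.0]), lam=np.zeros((1, 0)),
                               theta=np.array([2.0]), factor_sds=np.zeros(0),
                               factor_corr=np.eye(0))
        chisq = 2.0 * (saturated_loglik(sm) - marginal_loglik(params, sm, spec))
        assert chisq == pytest.approx(100 * (np.log(2.0) - 0.5), abs=1e-8)
        assert chisq == pytest.approx(19.31, abs=0.01)

    def test_chisq_identity_on_random_instances(self, specs):
        # chi2 computed from the moment formula equals 2(L_sat - L_model)
        rng = np.random.default_rng(0)
        spec = specs["three_factor"]
        gp = b.default_generating_parameters()
        rm = b.generate_responses(gp, 400, seed=13)
        sm = b.compute_sample_moments(rm)
        for _ in range(10):
            params = CFAParameters(
                nu=gp.intercepts + 0.1 * rng.standard_normal(12),
                lam=gp.lam * (1 + 0.2 * rng.standard_normal()),
                theta=gp.residual_variances * rng.uniform(0.5, 2.0, 12),
                factor_sds=rng.uniform(0.5, 2.0, 3),
                factor_corr=gp.factor_correlations,
            )
            direct = b.chisq_discrepancy(sm, implied_moments(params, spec))
            via_loglik = 2.0 * (saturated_loglik(sm) - marginal_loglik(params, sm, spec))
            assert direct == pytest.approx(via_loglik, abs=1e-8)

    def test_non_positive_definite_returns_neg_inf(self):
        spec, params = _one_factor(theta=(-3.0, -3.0))
        sm = SampleMoments(S=np.eye(2), ybar=np.zeros(2), N=10, p=2)
        assert marginal_loglik(params, sm, spec) == -np.inf


class TestStandardize:
    def test_direct_formula(self):
        spec, params = _one_factor(lam=(1.0, 2.0), theta=(1.0, 1.0))
        std = b.standardize(params, spec)
        assert std.lam[1, 0] == pytest.approx(2.0 / np.sqrt(5.0))
        assert std.theta[1] == pytest.approx(0.2)
        assert np.all(std.factor_sds == 1.0)

    def test_idempotent(self, gp, specs):
        params = CFAParameters(nu=gp.intercepts, lam=gp.lam, theta=gp.residual_variances,
                               factor_sds=np.ones(3), factor_corr=gp.factor_correlations)
        once = b.standardize(params, specs["three_factor"])
        twice = b.standardize(once, specs["three_factor"])
        np.testing.assert_allclose(once.lam, twice.lam, atol=1e-12)
        np.testing.assert_allclose(once.theta, twice.theta, atol=1e-12)

    def test_normalization_identity_and_invariant_correlations(self):
        rng = np.random.default_rng(1)
        spec, _ = _one_factor(p=3, lam=(1, 1, 1), theta=(1, 1, 1))
        spec = b.ModelSpec(("x0", "x1", "x2"), {"F": ("x0", "x1", "x2")})
        params = CFAParameters(nu=rng.normal(size=3),
                               lam=np.array([[1.0], [0.7], [1.3]]),
                               theta=rng.uniform(0.2, 2.0, 3),
                               factor_sds=np.array([1.7]), factor_corr=np.eye(1))
        std = b.standardize(params, spec)
        np.testing.assert_allclose(std.lam[:, 0] ** 2 + std.theta, 1.0, atol=1e-10)
        im_raw = implied_moments(params, spec).sigma_hat
        im_std = implied_moments(std, spec).sigma_hat
        d = np.sqrt(np.diag(im_raw))
        np.testing.assert_allclose(im_std, im_raw / np.outer(d, d), atol=1e-10)
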