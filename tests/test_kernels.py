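"""Kernel means, count likelihoods, ML fitting oracle checks, AIC ranking."""

import numpy as np
import pytest
from scipy import optimize

from dispersalfit import (
    DispersalKernel,
    KernelFit,
    compare_models,
    count_log_likelihood,
    fit_kernel,
    mean_exponential,
    mean_power,
)


class TestMeanFunctions:
    @pytest.mark.parametrize(
        "r0,beta,d,expect",
        [(15.5, -0.04, 0.0, 15.5), (7.0, 0.0, 123.0, 7.0), (15.5, -0.04, 50.0, 2.0977)],
    )
    def test_exponential(self, r0, beta, d, expect):
        assert mean_exponential(r0, beta, d) == pytest.approx(expect, rel=1e-4)

    @pytest.mark.parametrize(
        "r1,gamma,d,expect",
        [(4.3, -0.31, 1.0, 4.3), (9.0, -0.7, 1.0, 9.0), (4.3, -0.31, 113.0, 0.9931)],
    )
    def test_power(self, r1, gamma, d, expect):
        assert mean_power(r1, gamma, d) == pytest.approx(expect, rel=1e-4)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            mean_exponential(-1.0, -0.1, 1.0)
        with pytest.raises(ValueError):
            mean_power(4.3, -0.31, 0.0)


class TestCountLogLikelihood:
    def test_poisson_single_observation(self):
        # 2 ln 1.5 - 1.5 - ln 2!
        ll = count_log_likelihood([2], [1.0], "power", "poisson", 1.5, 0.0)
        assert ll == pytest.approx(-1.3822170, abs=1e-6)

    def test_negbin_zero_count_closed_form(self):
        # theta * ln(theta / (theta + mu)) with y = 0, mu = theta = 1
        ll = count_log_likelihood([0], [1.0], "power", "negbin", 1.0, 0.0, 1.0)
        assert ll == pytest.approx(-0.6931472, abs=1e-6)

    def test_negbin_approaches_poisson_at_large_theta(self, rng):
        y = rng.poisson(5.0, size=12)
        d = np.linspace(0.5, 20, 12)
        lp = count_log_likelihood(y, d, "exponential", "poisson", 6.0, -0.02)
        ln = count_log_likelihood(y, d, "exponential", "negbin", 6.0, -0.02, 1e6)
        assert ln == pytest.approx(lp, abs=1e-3)

    def test_invalid_params(self):
        with pytest.raises(ValueError):
            count_log_likelihood([1], [1.0], "power", "negbin", 1.0, 0.0, None)
        with pytest.raises(ValueError):
            count_log_likelihood([1], [0.0], "power", "poisson", 1.0, -0.5)
        with pytest.raises(ValueError):
            count_log_likelihood([-1], [1.0], "power", "poisson", 1.0, -0.5)


class TestFitKernel:
    def test_perfect_power_fit_is_exact(self):
        d = np.array([1.0, 2.0, 4.0, 8.0])
        y = np.array([16, 8, 4, 2])  # exactly 16 * D**-1
        fit = fit_kernel(d, y, "power", "poisson")
        assert fit.intercept == pytest.approx(16.0, abs=1e-6)
        assert fit.slope == pytest.approx(-1.0, abs=1e-6)

    def test_perfect_exponential_fit_is_exact(self):
        d = np.array([0.0, 10.0, 20.0])
        y = np.array([16, 8, 4])  # exactly 16 * exp(beta D), beta = ln(0.5)/10
        fit = fit_kernel(d, y, "exponential", "poisson")
        assert fit.intercept == pytest.approx(16.0, abs=1e-6)
        assert fit.slope == pytest.approx(np.log(0.5) / 10, abs=1e-6)

    @pytest.mark.parametrize("error_family", ["poisson", "negbin"])
    def test_matches_direct_likelihood_oracle(self, error_family):
        """The GLM route agrees with brute-force maximisation of the
        likelihood itself to 4 significant figures on a small dataset."""
        rng = np.random.default_rng(2024)
        d = np.repeat([0.05, 0.5, 5.0, 15.0, 50.0], 5)
        mu = 5.0 * d**-0.3
        y = rng.negative_binomial(3.0, 3.0 / (3.0 + mu))
        est = DispersalKernel("power", error_family).fit(d, y)
        assert est.fit_method_ == "statsmodels"

        def neg_ll(p):
            theta = np.exp(p[2]) if error_family == "negbin" else None
            try:
                return -count_log_likelihood(
                    y, d, "power", error_family, np.exp(p[0]), p[1], theta
                )
            except ValueError:
                return np.inf

        x0 = [np.log(y.mean() + 0.5), -0.1] + ([0.0] if error_family == "negbin" else [])
        sol = optimize.minimize(neg_ll, x0, method="Nelder-Mead",
                                options={"xatol": 1e-10, "fatol": 1e-10,
                                         "maxiter": 20000})
        assert est.intercept_ == pytest.approx(np.exp(sol.x[0]), rel=1e-4)
        assert est.slope_ == pytest.approx(sol.x[1], rel=1e-4)
        assert est.log_likelihood_ == pytest.approx(-sol.fun, abs=1e-6)
        if error_family == "negbin":
            assert est.dispersion_ == pytest.approx(np.exp(sol.x[2]), rel=1e-3)

    def test_loglik_is_local_maximum(self, settlement, rng):
        fit = fit_kernel(
            settlement.distance_km, settlement.total_gastropods, "power", "negbin"
        )
        ll_hat = count_log_likelihood(
            settlement.total_gastropods,
            settlement.distance_km,
            "power",
            "negbin",
            fit.intercept,
            fit.slope,
            fit.dispersion,
        )
        assert ll_hat == pytest.approx(fit.log_likelihood, abs=1e-5)
        for _ in range(25):
            pert = rng.normal(scale=[0.05, 0.02, 0.1])
            ll = count_log_likelihood(
                settlement.total_gastropods,
                settlement.distance_km,
                "power",
                "negbin",
                fit.intercept * np.exp(pert[0]),
                fit.slope + pert[1],
                fit.dispersion * np.exp(pert[2]),
            )
            assert ll <= ll_hat + 1e-8

    def test_poisson_limit_of_negbin_on_equidispersed_data(self):
        rng = np.random.default_rng(8)
        d = np.repeat([0.05, 0.5, 5.0, 15.0, 50.0], 40)
        y = rng.poisson(10.0 * np.exp(-0.04 * d))
        fp = fit_kernel(d, y, "exponential", "poisson")
        fn = fit_kernel(d, y, "exponential", "negbin")
        assert abs(fp.slope - fn.slope) < 0.01
        assert abs(np.log(fp.intercept) - np.log(fn.intercept)) < 0.01

    def test_aic_identity_and_ci_ordering(self, settlement):
        for err in ("poisson", "negbin"):
            fit = fit_kernel(
                settlement.distance_km, settlement.total_gastropods, "power", err
            )
            k = 2 if err == "poisson" else 3
            assert fit.aic == pytest.approx(2 * k - 2 * fit.log_likelihood, abs=1e-10)
            assert fit.intercept_ci[0] <= fit.intercept <= fit.intercept_ci[1]
            assert fit.slope_ci[0] <= fit.slope <= fit.slope_ci[1]

    def test_wald_ci_is_exponentiated_for_intercept(self, settlement):
        est = DispersalKernel("power", "poisson").fit(
            settlement.distance_km.to_numpy(), settlement.total_gastropods.to_numpy()
        )
        b0, se0 = est.linear_params_[0], est.linear_se_[0]
        z = 1.959963984540054
        assert est.intercept_ci_ == pytest.approx(
            (np.exp(b0 - z * se0), np.exp(b0 + z * se0))
        )

    def test_input_validation(self):
        with pytest.raises(ValueError, match="zero"):
            fit_kernel([1.0, 2.0, 4.0], [0, 0, 0], "power", "poisson")
        with pytest.raises(ValueError, match="distinct"):
            fit_kernel([1.0, 1.0, 2.0], [3, 4, 5], "power", "poisson")
        with pytest.raises(ValueError):
            fit_kernel([0.0, 1.0, 2.0], [3, 4, 5], "power", "poisson")
        with pytest.raises(ValueError):
            fit_kernel([1.0, 2.0, 3.0], [3, -1, 5], "power", "poisson")

    def test_sklearn_estimator_api(self, settlement):
        from sklearn.base import clone

        est = DispersalKernel(family="exponential", error_family="poisson")
        assert est.get_params() == {"family": "exponential", "error_family": "poisson"}
        est2 = clone(est).set_params(family="power")
        est2.fit(settlement.distance_km.to_numpy(),
                 settlement.total_gastropods.to_numpy())
        pred = est2.predict(np.array([[1.0], [10.0]]))
        assert pred[0] > pred[1] > 0


def _mkfit(family, error_family, aic, sig="samedata"):
    return KernelFit(
        family=family, error_family=error_family, intercept=5.0,
        intercept_ci=(4.0, 6.0), slope=-0.3, slope_ci=(-0.4, -0.2),
        dispersion=None if error_family == "poisson" else 2.0,
        log_likelihood=(2 * (2 if error_family == "poisson" else 3) - aic) / 2,
        aic=aic, n_obs=80, linear_params=(np.log(5.0), -0.3),
        linear_se=(0.1, 0.05), data_signature=sig,
    )


class TestCompareModels:
    def test_delta_aic_ranking(self):
        fits = [_mkfit("exponential", "negbin", 297.0),
                _mkfit("power", "negbin", 292.0)]
        out = compare_models(fits)
        assert list(out.family) == ["power", "exponential"]
        assert out.delta_aic.tolist() == [0.0, 5.0]
        assert out.best.tolist() == [True, False]

    def test_three_way_ranking(self):
        fits = [_mkfit("power", "negbin", 292.0),
                _mkfit("exponential", "negbin", 297.0),
                _mkfit("exponential", "poisson", 310.0)]
        out = compare_models(fits)
        assert out["rank"].tolist() == [1, 2, 3]
        assert out.delta_aic.tolist() == [0.0, 5.0, 18.0]

    def test_tie_break_keeps_declaration_order(self):
        fits = [_mkfit("exponential", "negbin", 300.0),
                _mkfit("power", "negbin", 300.0)]
        out = compare_models(fits)
        assert list(out.family) == ["exponential", "power"]
        assert out.delta_aic.tolist() == [0.0, 0.0]

    def test_different_data_rejected(self):
        fits = [_mkfit("power", "negbin", 292.0, sig="a"),
                _mkfit("exponential", "negbin", 297.0, sig="b")]
        with pytest.raises(ValueError, match="different observation sets"):
            compare_models(fits)
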