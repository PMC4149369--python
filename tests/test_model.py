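"""Transformed-GLM engine: IRLS oracles, likelihood, lambda profiling."""

import numpy as np
import pytest
from scipy import optimize, stats

from gsam import GSAM, GSAMSpec, boxcox, generate_gsam_data
from gsam.families import get_family, get_link
from gsam.model import irls_fit
from gsam.terms import intercept, log_area_power


def _random_problem(rng, n=30, p=3):
    X = np.column_stack([np.ones(n)] + [rng.uniform(0.2, 2.0, n)
                                        for _ in range(p - 1)])
    return X


class TestIRLSOracles:
    def test_normal_identity_equals_least_squares(self, rng):
        fam, link = get_family("normal"), get_link("identity")
        for _ in range(20):
            X = _random_problem(rng)
            z = rng.normal(X @ rng.uniform(-1, 2, 3), 0.5)
            beta, mu, eta, w, dev, conv, it = irls_fit(X, z, fam, link)
            ols, *_ = np.linalg.lstsq(X, z, rcond=None)
            assert conv
            assert np.allclose(beta, ols, atol=1e-10)
            assert np.allclose(w, 1.0) and np.allclose(mu, eta)

    @pytest.mark.parametrize("family, link", [
        ("gamma", "reciprocal"), ("gamma", "log"),
        ("inverse_gaussian", "inverse_squared"),
    ])
    def test_positive_families_match_numerical_mle(self, rng, family, link):
        """IRLS coefficients agree with a direct numerical maximizer of the
        family log-likelihood (beta does not depend on the dispersion)."""
        fam, lnk = get_family(family), get_link(link)
        for _ in range(5):
            X = _random_problem(rng, n=40, p=2)
            eta_true = 0.8 + 0.5 * X[:, 1]
            mu_true = lnk.inverse(eta_true)
            z = fam.sample(rng, mu_true, 0.02)
            beta, *_ , conv, it = irls_fit(X, z, fam, lnk)

            def nll(b):
                eta = X @ b
                with np.errstate(all="ignore"):
                    mu = lnk.inverse(eta)
                if not np.all(np.isfinite(mu)) or np.any(mu <= 0):
                    return 1e12
                return -fam.loglik(z, mu, 0.02)

            opt = optimize.minimize(nll, beta + rng.normal(0, 0.01, 2),
                                    method="Nelder-Mead",
                                    options={"xatol": 1e-12, "fatol": 1e-14,
                                             "maxiter": 20000})
            assert conv
            assert np.allclose(beta, opt.x, atol=1e-6)

    def test_statsmodels_cross_check(self, rng):
        """Independent GLM implementation reproduces the gamma fit."""
        sm = pytest.importorskip("statsmodels.api")
        X = _random_problem(rng, n=50, p=3)
        mu_true = 1.0 / (0.6 + 0.3 * X[:, 1] + 0.2 * X[:, 2])
        z = rng.gamma(20, mu_true / 20)
        beta, *_ = irls_fit(X, z, get_family("gamma"), get_link("reciprocal"))
        ref = sm.GLM(z, X, family=sm.families.Gamma(
            link=sm.genmod.families.links.InversePower())).fit()
        assert np.allclose(beta, ref.params, atol=1e-8)

    def test_underdetermined_rejected(self, rng):
        X = _random_problem(rng, n=3, p=3)
        with pytest.raises(ValueError, match="observations"):
            irls_fit(X, np.ones(3), get_family("normal"), get_link("identity"))

    def test_negative_response_rejected_for_gamma(self, rng):
        X = _random_problem(rng, n=10, p=2)
        z = rng.normal(0, 1, 10)
        with pytest.raises(ValueError, match="positive"):
            irls_fit(X, z, get_family("gamma"), get_link("log"))


class TestLoglik:
    def test_lambda_one_is_gaussian_loglik_of_residuals(self, hym,
                                                        selected_spec):
        res = GSAM(hym, selected_spec).fit()
        z = res.transformed.values
        r = z - res.fittedvalues
        phi = np.mean(r ** 2)
        expected = stats.norm.logpdf(r, scale=np.sqrt(phi)).sum()
        assert res.transformed.log_jacobian == 0.0
        assert res.llf == pytest.approx(expected, rel=1e-12)

    def test_lambda_recovery_within_lr_interval(self):
        """Data simulated at lambda0 = 0.5, n = 200, low noise: the LR
        interval for lambda covers the truth."""
        spec = GSAMSpec(terms=(intercept(), log_area_power(1)), lam=0.5)
        areas = np.geomspace(1, 100, 200)
        data = generate_gsam_data(spec, beta=[10.0, 3.0], lam=0.5,
                                  dispersion=0.5, areas=areas, seed=5)
        model = GSAM(data, GSAMSpec(terms=spec.terms, lam=None))
        trace = model.profile_lambda()
        assert trace.ci[0] <= 0.5 <= trace.ci[1]
        assert abs(trace.lambda_hat - 0.5) < 0.3


class TestProfile:
    def test_profile_matches_fixed_fits(self, hym, selected_spec):
        model = GSAM(hym, GSAMSpec(terms=selected_spec.terms, lam=None))
        grid = np.array([0.0, 0.5, 1.0, 1.5])
        trace = model.profile_lambda(grid=grid, refine=False)
        for lam, ll in zip(trace.grid, trace.profile_loglik):
            assert ll == pytest.approx(model.loglik_at(lam), rel=1e-12)

    def test_hymenoptera_interval_contains_one(self, hym, selected_spec):
        """No transformation needed for the Hymenoptera data: lambda = 1
        lies inside the 95% LR interval."""
        model = GSAM(hym, GSAMSpec(terms=selected_spec.terms, lam=None))
        trace = model.profile_lambda()
        assert trace.contains(1.0)
        assert trace.ci[0] <= trace.lambda_hat <= trace.ci[1]

    def test_ci_endpoints_solve_lr_equation(self, hym, selected_spec):
        model = GSAM(hym, GSAMSpec(terms=selected_spec.terms, lam=None))
        trace = model.profile_lambda()
        crit = stats.chi2.ppf(0.95, 1)
        for endpoint in trace.ci:
            drop = 2 * (trace.loglik_hat - model.loglik_at(endpoint))
            assert drop == pytest.approx(crit, abs=1e-3)

    def test_profiled_fit_attaches_trace(self, hym, selected_spec):
        res = GSAM(hym, GSAMSpec(terms=selected_spec.terms, lam=None)).fit()
        assert res.profiled and res.profile is not None
        assert res.lam == pytest.approx(res.profile.lambda_hat)
        assert res.k_params == res.df_model + 2


class TestLRTest:
    def test_statistic_zero_at_mle(self, hym, selected_spec):
        model = GSAM(hym, GSAMSpec(terms=selected_spec.terms, lam=None))
        trace = model.profile_lambda()
        w, p = model.lr_test_lambda(trace.lambda_hat)
        assert w == pytest.approx(0.0, abs=1e-6)
        assert p == pytest.approx(1.0, abs=1e-3)

    def test_statistic_nonnegative(self, hym, selected_spec):
        model = GSAM(hym, GSAMSpec(terms=selected_spec.terms, lam=None))
        for lam0 in (-1.0, 0.0, 0.5, 2.0):
            w, p = model.lr_test_lambda(lam0)
            assert w >= 0.0 and 0.0 <= p <= 1.0


class TestResults:
    def test_table_reproduction(self, hym, selected_spec):
        res = GSAM(hym, selected_spec).fit()
        assert np.allclose(res.params, [101.9707, 20.6625, -46.1669],
                           atol=5e-4)
        # residuals on the transformed scale sum to ~0 (intercept present)
        assert abs(np.sum(res.transformed.values
                          - res.fittedvalues)) < 1e-8

    def test_covariance_is_spd_and_matches_ols_formula(self, hym,
                                                       selected_spec):
        res = GSAM(hym, selected_spec).fit()
        X = res.model.exog()
        expected = res.scale * np.linalg.inv(X.T @ X)
        assert np.allclose(res.cov_params, expected)
        assert np.all(np.linalg.eigvalsh(res.cov_params) > 0)

    def test_serialization_roundtrip(self, hym, selected_spec):
        import json
        d = GSAM(hym, selected_spec).fit().to_dict()
        blob = json.loads(json.dumps(d))
        assert blob["n"] == 25 and len(blob["coefficients"]) == 3
        assert blob["converged"] is True

    def test_summary_mentions_terms(self, hym, selected_spec):
        text = GSAM(hym, selected_spec).fit().summary()
        assert "(ln A)^2" in text and "AIC" in text

    def test_parameter_recovery_bias_shrinks(self, rng):
        """Mean bias of the coefficient MLEs decreases with sample size."""
        spec = GSAMSpec(terms=(intercept(), log_area_power(1)), lam=1.0)
        truth = np.array([20.0, 15.0])
        bias = {}
        for n in (25, 100, 400):
            errs = []
            for rep in range(40):
                areas = np.geomspace(1, 100, n)
                data = generate_gsam_data(spec, truth, lam=1.0, dispersion=25.0,
                                          areas=areas,
                                          seed=int(rng.integers(2**31)))
                res = GSAM(data, spec).fit()
                errs.append(res.params - truth)
            bias[n] = np.abs(np.mean(errs, axis=0)).max()
        assert bias[400] < bias[25] + 0.5   # noise allowance
        assert bias[400] < 0.6
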