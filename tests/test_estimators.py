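import math

import numpy as np
import pytest
from scipy import stats

import skewcost as sc
from skewcost import Dataset, DGPSpec, generate


class TestOlsLog:
    def test_perfect_fit_both_retransforms(self, perfect_loglinear):
        for rt in ("normal", "smearing"):
            fr = sc.fit_ols_log(perfect_loglinear, rt)
            assert fr.beta0_hat == pytest.approx(0.0, abs=1e-12)
            assert fr.beta1_hat == pytest.approx(1.0, abs=1e-12)
            assert fr.aux["sigma2"] == pytest.approx(0.0, abs=1e-24)
            assert np.allclose(fr.yhat, perfect_loglinear.y, atol=1e-12)
        assert sc.fit_ols_log(perfect_loglinear, "smearing").aux["smearing"] == pytest.approx(1.0)

    def test_matches_statsmodels(self, lognormal_data):
        sm = pytest.importorskip("statsmodels.api")
        fr = sc.fit_ols_log(lognormal_data, "normal")
        res = sm.OLS(np.log(lognormal_data.y), sm.add_constant(lognormal_data.x)).fit()
        assert fr.beta0_hat == pytest.approx(res.params[0], abs=1e-10)
        assert fr.beta1_hat == pytest.approx(res.params[1], abs=1e-10)
        assert fr.aux["sigma2"] == pytest.approx(res.mse_resid, rel=1e-10)

    def test_retransform_factors_differ_but_agree_asymptotically(self):
        ds = generate(DGPSpec("lognormal", 1.0, 1.0, 100_000), 4)
        fn = sc.fit_ols_log(ds, "normal")
        fs = sc.fit_ols_log(ds, "smearing")
        # under truly log-normal errors both retransformations are consistent
        assert fs.aux["smearing"] == pytest.approx(math.exp(0.5 * fn.aux["sigma2"]), rel=0.02)

    def test_slope_unbiased_on_lognormal(self):
        b1 = []
        for r in range(300):
            ds = generate(DGPSpec("lognormal", 0.5, 1.0, 50), 600 + r)
            b1.append(sc.fit_ols_log(ds).beta1_hat)
        b1 = np.asarray(b1)
        se = b1.std(ddof=1) / math.sqrt(len(b1))
        assert abs(b1.mean() - 1.0) < 3 * se

    def test_rejects_nonpositive_y_and_constant_x(self):
        with pytest.raises(ValueError):
            sc.fit_ols_log(Dataset(x=np.array([0.1, 0.5, 0.9]), y=np.array([1.0, -1.0, 2.0])))
        with pytest.raises(ValueError):
            sc.fit_ols_log(Dataset(x=np.full(5, 0.3), y=np.ones(5)))

    def test_rejects_unknown_retransform(self, lognormal_data):
        with pytest.raises(ValueError):
            sc.fit_ols_log(lognormal_data, "duan-prime")


class TestGammaGlm:
    def test_saturated_two_point_design(self):
        # two distinct x values: the log-link fit reproduces group means exactly
        x = np.repeat([0.0, 1.0], 5)
        y = np.array([1.0, 2.0, 3.0, 2.0, 2.0, 5.0, 6.0, 7.0, 6.0, 6.0])
        fr = sc.fit_gamma_glm(Dataset(x=x, y=y))
        assert fr.yhat[:5] == pytest.approx(np.full(5, 2.0), abs=1e-7)
        assert fr.yhat[5:] == pytest.approx(np.full(5, 6.0), abs=1e-7)

    def test_score_identities(self, gamma_data):
        fr = sc.fit_gamma_glm(gamma_data)
        r = (gamma_data.y - fr.yhat) / fr.yhat
        assert abs(np.sum(r)) < 1e-6
        assert abs(np.sum(gamma_data.x * r)) < 1e-6

    def test_matches_statsmodels(self, gamma_data):
        sm = pytest.importorskip("statsmodels.api")
        fr = sc.fit_gamma_glm(gamma_data)
        res = sm.GLM(
            gamma_data.y,
            sm.add_constant(gamma_data.x),
            family=sm.families.Gamma(link=sm.families.links.Log()),
        ).fit()
        assert fr.beta0_hat == pytest.approx(res.params[0], abs=1e-8)
        assert fr.beta1_hat == pytest.approx(res.params[1], abs=1e-8)
        assert fr.aux["dispersion"] == pytest.approx(res.pearson_chi2 / res.df_resid, rel=1e-6)

    def test_consistency_large_sample(self):
        # x-dependent scale with fixed shape is a log-link mean model with
        # an intercept shift of ln(shape)
        ds = generate(DGPSpec("gamma", 4.0, 1.0, 1_000_000), 8)
        fr = sc.fit_gamma_glm(ds, compute_aic=False)
        assert abs(fr.beta1_hat - 1.0) < 0.01
        assert fr.beta0_hat == pytest.approx(ds.spec.beta0 + math.log(4.0), abs=0.01)

    def test_profiled_shape_near_truth(self, gamma_data):
        fr = sc.fit_gamma_glm(gamma_data)
        assert fr.aux["shape_ml"] == pytest.approx(2.0, rel=0.3)
        assert np.isfinite(fr.aic)


class TestWeibullReg:
    def test_matches_lifelines(self, weibull_data):
        lifelines = pytest.importorskip("lifelines")
        pd = pytest.importorskip("pandas")
        fr = sc.fit_weibull_reg(weibull_data)
        aft = lifelines.WeibullAFTFitter()
        aft.fit(pd.DataFrame({"T": weibull_data.y, "x": weibull_data.x}), duration_col="T")
        assert fr.beta0_hat == pytest.approx(aft.params_[("lambda_", "Intercept")], abs=1e-4)
        assert fr.beta1_hat == pytest.approx(aft.params_[("lambda_", "x")], abs=1e-4)
        assert fr.aux["shape"] == pytest.approx(math.exp(aft.params_[("rho_", "Intercept")]), rel=1e-4)

    def test_exponential_special_case(self):
        # gamma with shape 1 is exponential, i.e. a Weibull with shape 1
        ds = generate(DGPSpec("gamma", 1.0, 1.0, 20_000), 13)
        fr = sc.fit_weibull_reg(ds)
        assert fr.aux["shape"] == pytest.approx(1.0, abs=0.02)
        assert fr.beta1_hat == pytest.approx(1.0, abs=0.05)

    def test_scale_prediction_bias_is_analytic(self):
        # predicting the scale exp(eta) under shape 0.5 misses the factor
        # Gamma(3) = 2, so the population MPE is 1 - 1/2
        ds = generate(DGPSpec("weibull", 0.5, 1.0, 200_000), 21)
        fr = sc.fit_weibull_reg(ds)
        assert sc.mpe(ds.y, fr.yhat) == pytest.approx(0.5, abs=0.02)

    def test_mean_correction_flag(self, weibull_data):
        base = sc.fit_weibull_reg(weibull_data)
        corr = sc.fit_weibull_reg(weibull_data, mean_correction=True)
        from scipy.special import gamma as g

        factor = g(1.0 + 1.0 / base.aux["shape"])
        assert np.allclose(corr.yhat, base.yhat * factor, rtol=1e-10)


def _cox_partial_loglik(beta, x, y):
    """Brute-force Breslow partial log-likelihood (independent oracle)."""
    order = np.argsort(y)
    x, y = x[order], y[order]
    ll = 0.0
    for i in range(len(y)):
        risk = y >= y[i]
        ll += beta * x[i] - math.log(np.sum(np.exp(beta * x[risk])))
    return ll


class TestCoxPh:
    def test_grid_search_oracle_n3(self):
        ds = Dataset(x=np.array([0.0, 1.0, 0.4]), y=np.array([2.0, 1.0, 3.0]))
        fr = sc.fit_cox_ph(ds)
        grid = np.linspace(-20, 20, 4001)
        ll = [_cox_partial_loglik(b, ds.x, ds.y) for b in grid]
        best = grid[int(np.argmax(ll))]
        fine = np.linspace(best - 0.02, best + 0.02, 4001)
        llf = [_cox_partial_loglik(b, ds.x, ds.y) for b in fine]
        assert fr.beta1_hat == pytest.approx(fine[int(np.argmax(llf))], abs=1e-4)

    def test_matches_lifelines(self, weibull_data):
        lifelines = pytest.importorskip("lifelines")
        pd = pytest.importorskip("pandas")
        fr = sc.fit_cox_ph(weibull_data)
        df = pd.DataFrame({"T": weibull_data.y, "x": weibull_data.x})
        cph = lifelines.CoxPHFitter()
        cph.fit(df, duration_col="T")
        assert fr.beta1_hat == pytest.approx(float(cph.params_.iloc[0]), abs=1e-6)
        # restricted-mean predictions from the lifelines survival curves
        times = np.unique(weibull_data.y)
        sf = cph.predict_survival_function(df, times=times).to_numpy()
        dt = np.diff(times)
        rmean = times[0] + sf[:-1].T @ dt
        assert np.allclose(fr.yhat, rmean, rtol=1e-5)

    def test_constant_covariate_restricted_mean(self):
        rng = np.random.default_rng(1)
        y = rng.gamma(2.0, 0.5, 200)
        fr = sc.fit_cox_ph(Dataset(x=np.full(200, 0.3), y=y))
        assert fr.beta1_hat == 0.0
        assert "constant_covariate" in fr.flags
        # Breslow exponential survival integrates close to the sample mean
        assert fr.yhat[0] == pytest.approx(y.mean(), rel=0.02)
        assert np.allclose(fr.yhat, fr.yhat[0])

    def test_order_invariance(self, weibull_data):
        fr = sc.fit_cox_ph(weibull_data)
        perm = np.random.default_rng(2).permutation(weibull_data.n)
        shuffled = Dataset(x=weibull_data.x[perm], y=weibull_data.y[perm])
        fs = sc.fit_cox_ph(shuffled)
        assert fs.beta1_hat == pytest.approx(fr.beta1_hat, abs=1e-12)
        assert np.allclose(fs.yhat, fr.yhat[perm], rtol=1e-12)

    def test_intercept_flagged_undefined(self, weibull_data):
        fr = sc.fit_cox_ph(weibull_data)
        assert fr.beta0_hat == 0.0
        assert "beta0_undefined" in fr.flags

    def test_predictions_skippable(self, weibull_data):
        fr = sc.fit_cox_ph(weibull_data, predictions=False)
        assert np.all(np.isnan(fr.yhat))
        assert "predictions_skipped" in fr.flags


class TestPhDiagnostic:
    def test_undefined_cases(self):
        ds = Dataset(x=np.full(10, 0.5), y=np.linspace(1, 2, 10))
        fr = sc.fit_cox_ph(ds)
        with pytest.warns(UserWarning):
            assert math.isnan(sc.ph_diagnostic(fr, ds))
        ds2 = Dataset(x=np.linspace(0, 1, 10), y=np.array([1.0, 2.0] * 5))
        fr2 = sc.fit_cox_ph(ds2)
        with pytest.warns(UserWarning):
            assert math.isnan(sc.ph_diagnostic(fr2, ds2))

    def test_requires_cox_fit(self, gamma_data):
        fr = sc.fit_gamma_glm(gamma_data)
        with pytest.raises(ValueError):
            sc.ph_diagnostic(fr, gamma_data)

    def test_calibration_under_exact_ph(self):
        # under the proportional-hazards generating process the test should
        # reject at about its nominal level, with near-uniform p-values
        ps = []
        for r in range(300):
            ds = generate(DGPSpec("weibull", 1.0, 1.0, 100), 30_000 + r)
            fr = sc.fit_cox_ph(ds, predictions=False)
            ps.append(sc.ph_diagnostic(fr, ds))
        ps = np.asarray(ps)
        rate = np.mean(ps < 0.05)
        assert 0.01 <= rate <= 0.11  # 0.05 +/- ~3 binomial SEs
        assert stats.kstest(ps, "uniform").pvalue > 0.005


def test_dispatcher_rejects_unknown(lognormal_data):
    with pytest.raises(ValueError):
        sc.fit(lognormal_data, "tobit")


def test_contract_parity_across_estimators(lognormal_data):
    # every estimator exposes a slope and positive in-sample predictions
    for est in sc.ESTIMATORS:
        fr = sc.fit(lognormal_data, est)
        assert len(fr.yhat) == lognormal_data.n
        assert np.all(fr.yhat > 0)
        assert np.isfinite(fr.beta1_hat)


def test_predictions_frame(tmp_path, gamma_data):
    from skewcost.estimators import predictions_to_frame

    fr = sc.fit_gamma_glm(gamma_data)
    df = predictions_to_frame(gamma_data, fr)
    assert list(df.columns) == ["y", "yhat", "residual"]
    assert np.allclose(df["residual"], gamma_data.y - fr.yhat)
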