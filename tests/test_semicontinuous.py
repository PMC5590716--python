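"""Two-part mixed models: likelihoods, bridge marginalisation, marginal means."""

import numpy as np
import pandas as pd
import pytest
from scipy.integrate import quad
from scipy.special import expit

import twopartlong as tpl
from twopartlong.data import LongitudinalDataset, TransformSpec, build_designs
from twopartlong.distributions import (
    BridgeParams,
    bridge_inverse_cdf,
    bridge_pdf,
)
from twopartlong.estimation import FitResult
from twopartlong.semicontinuous import (
    BridgeTwoPartParams,
    TwoPartParams,
    conditional_coeffs,
    conditional_marginal_mean,
    conditional_mean_bounds,
    fit_twopart,
    loglik_bridge_twopart,
    loglik_twopart,
    marginal_contrast,
    overall_marginal_mean,
    overall_mean_bounds,
)


def single_visit_ds(y=0.0):
    return LongitudinalDataset(pd.DataFrame(
        {"subject": [1], "time": [0.0], "outcome": [y]}))


class TestTwoPartLoglik:
    def test_no_random_effects_closed_form(self):
        # one zero observation, theta = 0, no random effects: P = 1/2
        ds = single_visit_ds(0.0)
        d = build_designs(ds)
        params = TwoPartParams([0.0], [0.0], tpl.BivariateNormalRE(0.0, 0.0, 0.0),
                               1.0)
        assert loglik_twopart(ds, d, params) == pytest.approx(np.log(0.5), abs=1e-10)

    def test_separates_at_zero_correlation(self, twopart_panel):
        ds, designs, params, _ = twopart_panel
        p0 = TwoPartParams(params.theta, params.beta,
                           tpl.BivariateNormalRE(params.re.var_u,
                                                 params.re.var_v, 0.0),
                           params.resid_var, params.transform)
        joint = loglik_twopart(ds, designs, p0, 25)
        # independent reconstruction of the two separate parts
        from twopartlong.quadrature import log_marginal_subjects_1d
        from twopartlong.semicontinuous import _log_sigmoid, _segment_starts

        y = ds.outcome
        z = (y > 0).astype(float)
        gy = np.where(y > 0, params.transform.forward(np.maximum(y, 1e-300)), 0.0)
        codes = ds.subject_codes
        starts = _segment_starts(codes)
        eta_b = designs.X_binary @ params.theta
        eta_c = designs.X_intensity @ params.beta
        su, sv = np.sqrt(p0.re.var_u), np.sqrt(p0.re.var_v)

        def cond_b(a):
            lp = eta_b[:, None] + su * a[codes]
            lb = np.where(z[:, None] > 0, _log_sigmoid(lp), _log_sigmoid(-lp))
            return np.add.reduceat(lb, starts, axis=0)

        def cond_c(a):
            r = gy[:, None] - eta_c[:, None] - sv * a[codes]
            lc = z[:, None] * (-0.5 * np.log(2 * np.pi * params.resid_var)
                               - r**2 / (2 * params.resid_var))
            return np.add.reduceat(lc, starts, axis=0)

        sep = (log_marginal_subjects_1d(cond_b, ds.n_subjects, 25).sum()
               + log_marginal_subjects_1d(cond_c, ds.n_subjects, 25).sum())
        assert joint == pytest.approx(sep, abs=1e-10)

    def test_matches_monte_carlo_oracle(self, twopart_panel):
        ds, designs, params, _ = twopart_panel
        sub = ds.df[ds.df["subject"] < 25]
        ds_small = LongitudinalDataset(sub)
        d_small = build_designs(ds_small, ("g",), ("g",))
        ll = loglik_twopart(ds_small, d_small, params, 30, per_subject=True)

        rng = np.random.default_rng(8)
        n_mc = 40000
        L = np.linalg.cholesky(params.re.cov)
        z2 = rng.standard_normal((n_mc, 2)) @ L.T
        y = ds_small.outcome
        z = y > 0
        gy = np.where(z, np.log(np.maximum(y, 1e-300)), 0.0)
        eta_b = d_small.X_binary @ params.theta
        eta_c = d_small.X_intensity @ params.beta
        codes = ds_small.subject_codes
        for i in range(ds_small.n_subjects):
            m = codes == i
            lp = eta_b[m][None, :] + z2[:, [0]]
            lb = np.where(z[m][None, :], -np.logaddexp(0, -lp), -np.logaddexp(0, lp))
            r = gy[m][None, :] - eta_c[m][None, :] - z2[:, [1]]
            lc = z[m][None, :] * (-0.5 * np.log(2 * np.pi * params.resid_var)
                                  - r**2 / (2 * params.resid_var))
            vals = np.exp(np.sum(lb + lc, axis=1))
            mc = vals.mean()
            se = vals.std(ddof=1) / np.sqrt(n_mc)
            assert abs(np.exp(ll[i]) - mc) < 3 * se + 1e-12

    def test_row_order_invariance(self, twopart_panel):
        ds, designs, params, _ = twopart_panel
        perm = ds.df.sample(frac=1.0, random_state=3)
        ds2 = LongitudinalDataset(perm)
        d2 = build_designs(ds2, ("g",), ("g",))
        l1 = loglik_twopart(ds, designs, params, 20)
        l2 = loglik_twopart(ds2, d2, params, 20)
        assert l1 == pytest.approx(l2, abs=1e-8)


class TestBridgeMarginalisation:
    def marginal_prob(self, eta, phi):
        return quad(lambda b: expit(eta / phi + b) * bridge_pdf(b, phi),
                    -np.inf, np.inf)[0]

    def test_symmetric_case(self):
        assert self.marginal_prob(0.0, 0.37) == pytest.approx(0.5, abs=1e-10)

    def test_defining_identity_at_published_values(self):
        # marginal occurrence probability is logistic in the marginal predictor
        assert self.marginal_prob(0.62, 0.4861) == pytest.approx(
            expit(0.62), abs=1e-6)

    def test_identity_over_random_pairs(self):
        rng = np.random.default_rng(12)
        for _ in range(20):
            eta = rng.uniform(-2.5, 2.5)
            phi = rng.uniform(0.15, 0.9)
            assert abs(self.marginal_prob(eta, phi) - expit(eta)) < 1e-6

    def test_bridge_loglik_reduces_to_marginal_logistic_when_rho_zero(self):
        # a single zero observation: the marginal likelihood equals
        # 1 - logit^{-1}(X theta) by the bridge's defining property
        ds = single_visit_ds(0.0)
        d = build_designs(ds)
        params = BridgeTwoPartParams([0.8], [0.0], BridgeParams(0.4861),
                                     0.5, 0.0, 1.0)
        ll = loglik_bridge_twopart(ds, d, params, 60)
        assert ll == pytest.approx(np.log(1 - expit(0.8)), abs=1e-6)


class TestConditionalCoefficients:
    def bridge_fit(self, theta, phi, cov=None):
        names = tuple([f"binary:c{i}" for i in range(len(theta))]
                      + ["intensity:intercept", "phi", "var_v", "rho", "resid_var"])
        k = len(names)
        est = np.array(list(theta) + [0.0, phi, 0.3, 0.9, 0.1])
        fit = FitResult(names, est, -1.0, cov if cov is not None else np.zeros((k, k)),
                        True, 10, 10, 20)
        return fit

    def test_attenuation_ratios_from_published_estimates(self):
        fit = self.bridge_fit([0.62, 0.47, 0.81], 0.4861)
        cond, _ = conditional_coeffs(fit)
        assert round(cond[0], 2) == 1.28
        assert round(cond[1], 2) == 0.97
        # the interaction row prints 1.66; input rounding allows 0.02
        assert cond[2] == pytest.approx(1.66, abs=0.02)

    def test_no_attenuation_at_phi_one(self):
        fit = self.bridge_fit([0.5], 0.999999)
        cond, _ = conditional_coeffs(fit)
        assert cond[0] == pytest.approx(0.5, abs=1e-4)

    def test_delta_method_se(self):
        # diagonal covariance: Var(theta/phi) =
        # Var(theta)/phi^2 + theta^2 Var(phi)/phi^4
        theta, phi = 0.62, 0.4861
        se_t, se_p = 0.18, 0.03
        cov = np.zeros((6, 6))
        cov[0, 0] = se_t**2
        cov[2, 2] = se_p**2
        fit = self.bridge_fit([theta], phi, cov)
        _, se = conditional_coeffs(fit)
        expect = np.sqrt(se_t**2 / phi**2 + theta**2 * se_p**2 / phi**4)
        assert se[0] == pytest.approx(expect, rel=1e-10)

    def test_implied_bridge_variance_from_phi(self):
        assert tpl.bridge_variance(0.4861) == pytest.approx(10.64, abs=0.02)


class TestMarginalMeans:
    def params(self, rho, transform="identity"):
        return BridgeTwoPartParams([0.6], [0.8], BridgeParams(0.5), 0.5, rho,
                                   0.2, TransformSpec(transform))

    def test_conditional_mean_is_linear_predictor_at_rho_zero(self):
        p = self.params(0.0)
        assert conditional_marginal_mean([1.0], [1.0], p) == pytest.approx(0.8)

    def test_conditional_mean_within_bounds(self):
        p = self.params(0.9)
        val = conditional_marginal_mean([1.0], [1.0], p)
        lo, hi = conditional_mean_bounds([1.0], [1.0], p)
        assert lo <= val <= hi
        pn = self.params(-0.9)
        valn = conditional_marginal_mean([1.0], [1.0], pn)
        lon, hin = conditional_mean_bounds([1.0], [1.0], pn)
        assert lon <= valn <= hin

    def test_conditional_mean_against_monte_carlo(self):
        p = self.params(0.7)
        val = conditional_marginal_mean([1.0], [1.0], p)
        rng = np.random.default_rng(21)
        n = 10**6
        b, v = tpl.sample_bridge_normal_pair(p.rho, p.var_v, p.bridge.phi, n,
                                             seed=rng)
        occ = rng.random(n) < expit(0.6 / 0.5 + b)
        mc_vals = 0.8 + v[occ]
        mc = mc_vals.mean()
        se = mc_vals.std(ddof=1) / np.sqrt(occ.sum())
        assert abs(val - mc) < 3 * se

    def test_overall_mean_factorises_at_rho_zero(self):
        p = self.params(0.0)
        assert overall_marginal_mean([1.0], [1.0], p) == pytest.approx(
            expit(0.6) * 0.8, abs=1e-10)

    def test_overall_mean_within_bounds(self):
        p = self.params(0.8)
        val = overall_marginal_mean([1.0], [1.0], p)
        lo, hi = overall_mean_bounds([1.0], [1.0], p)
        assert lo <= val <= hi

    def test_overall_mean_log_transform_against_monte_carlo(self):
        p = self.params(0.6, transform="log")
        val = overall_marginal_mean([1.0], [1.0], p)
        rng = np.random.default_rng(22)
        n = 10**6
        b, v = tpl.sample_bridge_normal_pair(p.rho, p.var_v, p.bridge.phi, n,
                                             seed=rng)
        occ = rng.random(n) < expit(0.6 / 0.5 + b)
        yv = np.exp(0.8 + v + np.sqrt(p.resid_var) * rng.standard_normal(n))
        mc_vals = np.where(occ, yv, 0.0)
        mc = mc_vals.mean()
        se = mc_vals.std(ddof=1) / np.sqrt(n)
        assert abs(val - mc) < 3 * se


class TestMarginalContrast:
    def fit(self, cov_scale=1.0):
        names = ("binary:intercept", "binary:g", "intensity:intercept",
                 "intensity:g", "phi", "var_v", "rho", "resid_var")
        est = np.array([0.6, 0.3, 0.8, 0.2, 0.5, 0.5, 0.6, 0.2])
        from twopartlong.estimation import ParamTransform
        pt = ParamTransform(names, ("identity",) * 4 + ("logit", "log", "atanh", "log"))
        xu = pt.to_unconstrained(est)
        fit = FitResult(names, est, -1.0, np.eye(8) * cov_scale, True, 50, 200, 20,
                        x_unconstrained=xu, transform=pt,
                        cov_unconstrained=np.eye(8) * cov_scale * 0.01)
        fit.extra["binary_names"] = ["intercept", "g"]
        fit.extra["intensity_names"] = ["intercept", "g"]
        fit.extra["transform"] = "identity"
        return fit

    def test_equal_settings_give_zero(self):
        res = marginal_contrast(self.fit(), {"g": 1.0}, {"g": 1.0},
                                n_draws=200, seed=1)
        assert res["estimate"] == pytest.approx(0.0, abs=1e-12)
        assert res["ci"][0] == pytest.approx(0.0, abs=1e-12)
        assert res["ci"][1] == pytest.approx(0.0, abs=1e-12)

    def test_degenerate_covariance_gives_plugin(self):
        fit = self.fit()
        fit.cov_unconstrained = np.zeros((8, 8))
        res = marginal_contrast(fit, {"g": 1.0}, {"g": 0.0}, n_draws=100, seed=1)
        assert res["n_draws"] == 0
        assert res["ci"][0] == res["ci"][1] == res["estimate"]

    def test_interval_brackets_plugin_estimate(self):
        res = marginal_contrast(self.fit(), {"g": 1.0}, {"g": 0.0},
                                n_draws=500, seed=2)
        assert res["ci"][0] < res["estimate"] < res["ci"][1]


class TestFitTwoPart:
    def test_independence_path_matches_joint_path(self, twopart_panel):
        ds, designs, _, _ = twopart_panel
        sep = fit_twopart(ds, designs, quad_order=10, rho_fixed=0.0)
        joint = fit_twopart(ds, designs, quad_order=10, rho_fixed=0.0,
                            robust=True)  # robust forces the joint code path
        assert sep.loglik == pytest.approx(joint.loglik, abs=1e-4)

    def test_estimator_interface(self, twopart_panel):
        ds, _, params, _ = twopart_panel
        est = tpl.TwoPartMixedModel(binary_terms=("g",), intensity_terms=("g",),
                                    quad_order=10)
        est.fit(ds)
        assert est.converged_
        assert est.loglik_ == pytest.approx(est.result_.loglik)
        got = est.get_params()
        assert got["quad_order"] == 10
        # fitted coefficients within a loose sanity band of the truth
        assert abs(est.coef_[0] - params.theta[0]) < 1.0
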