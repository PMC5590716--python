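"""Mover-stayer frailty models: likelihood anchors, boundary inference, GoF."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import twopartlong as tpl
from twopartlong.data import LongitudinalDataset, build_designs
from twopartlong.distributions import MoverStayerRE
from twopartlong.moverstayer import (
    MoverStayerParams,
    boundary_lrt_pvalue,
    empirical_bayes,
    fit_ms,
    loglik_ms,
    ms_subject_loglik,
    nb_obs_kernel,
    pearson_gof,
    pearson_statistic,
    profile_pi,
)
from twopartlong.simulate import simulate_ms


def one_visit_ds(y=0.0, offset=1.0):
    return LongitudinalDataset(pd.DataFrame(
        {"subject": [1], "time": [1.0], "outcome": [y], "offset": [offset]}))


def gamma_params(pi=0.0, disp=1.0, rate=1.0, beta=()):
    return MoverStayerParams(rate, list(beta),
                             MoverStayerRE("gamma", stayer_prob=pi,
                                           gamma_dispersion=disp))


class TestSubjectLoglik:
    def test_exponential_frailty_closed_form(self):
        # y = 0, Lambda = 1, Exp(1) frailty, no stayers:
        # L = int e^{-u} e^{-u} du = 1/2
        ds = one_visit_ds(0.0)
        d = build_designs(ds)
        ll = loglik_ms(ds, d, gamma_params(pi=0.0))
        assert np.exp(ll) == pytest.approx(0.5, abs=1e-10)

    def test_stayer_atom_added_for_all_zero_subject(self):
        # same subject with pi = 0.2: L = 0.2 + 0.8 * 0.5
        ds = one_visit_ds(0.0)
        d = build_designs(ds)
        ll = loglik_ms(ds, d, gamma_params(pi=0.2))
        assert np.exp(ll) == pytest.approx(0.6, abs=1e-10)

    def test_atom_excluded_for_subject_with_events(self):
        # a subject with damage cannot be a stayer: only the scaled mover
        # integral contributes
        ds = one_visit_ds(2.0)
        d = build_designs(ds)
        l_pi = loglik_ms(ds, d, gamma_params(pi=0.3))
        l_0 = loglik_ms(ds, d, gamma_params(pi=0.0))
        assert l_pi == pytest.approx(np.log(0.7) + l_0, abs=1e-10)

    def test_single_subject_wrapper(self):
        df = pd.DataFrame({"subject": [7, 7], "time": [1.0, 2.0],
                           "outcome": [0.0, 3.0], "offset": [1.0, 1.0]})
        ll = ms_subject_loglik(df, lambda d: build_designs(d), gamma_params(pi=0.1))
        full = loglik_ms(LongitudinalDataset(df),
                         build_designs(LongitudinalDataset(df)),
                         gamma_params(pi=0.1))
        assert ll == pytest.approx(full, abs=1e-12)

    def test_gamma_closed_form_equals_quadrature(self):
        # the module's correctness anchor, on a batch of random subjects
        params = MoverStayerParams(
            0.7, [0.3], MoverStayerRE("gamma", stayer_prob=0.25,
                                      gamma_dispersion=1.4))
        ds, _ = simulate_ms(params, 25,
                            covariates={"a": lambda r, n: r.binomial(1, 0.5, n).astype(float)},
                            intensity_terms=("a",), seed=41)
        d = build_designs(ds, intensity_terms=("a",))
        closed = loglik_ms(ds, d, params, per_subject=True, use_closed_form=True)
        quadr = loglik_ms(ds, d, params, n_quad=96, per_subject=True,
                          use_closed_form=False)
        assert np.max(np.abs(closed - quadr)) < 1e-8

    def test_pi_zero_reproduces_plain_frailty_model(self):
        params0 = gamma_params(pi=0.0, disp=2.0)
        ds, _ = simulate_ms(params0, 30, seed=5)
        d = build_designs(ds)
        ig0 = MoverStayerParams(1.0, [], MoverStayerRE("inverse_gaussian",
                                                       stayer_prob=0.0,
                                                       ig_shape=0.8))
        # with pi = 0 the mover-stayer likelihood is exactly the frailty
        # integral, no mixture bookkeeping left over
        from twopartlong.moverstayer import _mover_integrals
        ll = loglik_ms(ds, d, ig0, per_subject=True)
        direct = _mover_integrals(ds, d, ig0)
        assert np.allclose(ll, direct, atol=1e-12)


class TestNbKernel:
    def test_poisson_limit(self):
        assert nb_obs_kernel(0, 1.0, 1.0, 0.0) == pytest.approx(np.exp(-1), abs=1e-12)

    def test_unit_dispersion_geometric_tail(self):
        # NB with unit-mean gamma mixing, dispersion 1: P(0 | mean 1) = 1/2
        assert nb_obs_kernel(0, 1.0, 1.0, 1.0) == pytest.approx(0.5, abs=1e-12)
        # cross-check by numeric integration over the gamma mixing law
        from scipy.integrate import quad
        from twopartlong.distributions import unit_gamma_pdf
        val, _ = quad(lambda g: np.exp(-g) * unit_gamma_pdf(g, 1.0), 0, np.inf)
        assert nb_obs_kernel(0, 1.0, 1.0, 1.0) == pytest.approx(val, abs=1e-9)

    def test_sums_to_one(self):
        y = np.arange(0, 500)
        total = nb_obs_kernel(y, 2.0, 1.5, 0.7).sum()
        assert total == pytest.approx(1.0, abs=1e-10)

    def test_zinb_special_case_of_nb_ms_gamma(self):
        # patient-level gamma dispersion -> 0 degenerates the frailty to a
        # point mass at one, leaving patient-level zero inflation over a
        # negative-binomial kernel: the ZINB model
        base = MoverStayerParams(
            0.8, [0.3], MoverStayerRE("gamma", stayer_prob=0.25,
                                      gamma_dispersion=1.2),
            obs_dispersion=0.7)
        ds, _ = simulate_ms(base, 40,
                            covariates={"a": lambda r, n: r.binomial(1, 0.5, n).astype(float)},
                            intensity_terms=("a",), seed=53)
        d = build_designs(ds, intensity_terms=("a",))
        import dataclasses
        tiny = dataclasses.replace(
            base, re=MoverStayerRE("gamma", stayer_prob=0.25,
                                   gamma_dispersion=1e-8))
        ll = loglik_ms(ds, d, tiny, per_subject=True)
        # direct ZINB: frailty fixed at u = 1
        from twopartlong.moverstayer import _log_lambda, _log_nb_kernel
        from twopartlong.semicontinuous import _segment_starts
        lam = np.exp(_log_lambda(ds, d, tiny))
        starts = _segment_starts(ds.subject_codes)
        lk = np.add.reduceat(_log_nb_kernel(ds.outcome, lam, 0.7), starts)
        S = np.add.reduceat(ds.outcome, starts)
        direct = np.where(S > 0, np.log(0.75) + lk,
                          np.logaddexp(np.log(0.25), np.log(0.75) + lk))
        assert np.max(np.abs(ll - direct)) < 1e-6

    def test_nb_dispersion_zero_equals_poisson_loglik(self):
        params_p = gamma_params(pi=0.2, disp=1.2, rate=0.8, beta=[0.3])
        ds, _ = simulate_ms(params_p, 40,
                            covariates={"a": lambda r, n: r.binomial(1, 0.5, n).astype(float)},
                            intensity_terms=("a",), seed=13)
        d = build_designs(ds, intensity_terms=("a",))
        import dataclasses
        params_nb0 = dataclasses.replace(params_p, obs_dispersion=0.0)
        a = loglik_ms(ds, d, params_p, use_closed_form=False)
        b = loglik_ms(ds, d, params_nb0, use_closed_form=False)
        assert a == pytest.approx(b, abs=1e-10)


class TestFit:
    def test_cp_stayer_probability_is_exp_minus_rate(self):
        params = MoverStayerParams(
            1.0, [], MoverStayerRE("compound_poisson", cp_rate=0.7,
                                   cp_summand_rate=2.5))
        ds, _ = simulate_ms(params, 250, seed=19)
        d = build_designs(ds)
        fit = fit_ms(ds, d, "compound_poisson", compute_cov=False)
        assert fit.extra["stayer_prob"] == pytest.approx(
            np.exp(-fit["cp_rate"]), abs=1e-15)

    def test_boundary_estimate_flagged(self):
        # data without a stayer population: pi is driven to the boundary
        params = gamma_params(pi=0.0, disp=4.0, rate=0.3)
        ds, _ = simulate_ms(params, 200, seed=23)
        d = build_designs(ds)
        fit = fit_ms(ds, d, "gamma", compute_cov=False)
        if fit.extra["stayer_prob"] < 0.01:
            assert fit.extra.get("pi_boundary")
            assert "profile_pi" in fit.message


@pytest.fixture(scope="module")
def stayer_panel():
    params = MoverStayerParams(
        1.2, [], MoverStayerRE("inverse_gaussian", stayer_prob=0.5,
                               ig_shape=1.5))
    ds, _ = simulate_ms(params, 400, seed=29)
    return ds, build_designs(ds)


class TestProfilePi:
    def test_profile_maximum_near_truth(self, stayer_panel):
        ds, d = stayer_panel
        prof = profile_pi(ds, d, "inverse_gaussian",
                          pi_grid=np.linspace(0, 0.9, 19))
        assert abs(prof["pi_hat"] - 0.5) <= 0.1
        step = 0.9 / 18  # grid resolution bounds the CI endpoints
        assert prof["ci"][0] - step <= 0.5 <= prof["ci"][1] + step

    def test_profile_consistent_with_free_fit(self, stayer_panel):
        ds, d = stayer_panel
        free = fit_ms(ds, d, "inverse_gaussian", compute_cov=False)
        pi_hat = free.extra["stayer_prob"]
        prof = profile_pi(ds, d, "inverse_gaussian", pi_grid=[pi_hat])
        assert prof["loglik_max"] == pytest.approx(free.loglik, abs=1e-6)

    def test_cp_family_rejected(self, stayer_panel):
        ds, d = stayer_panel
        with pytest.raises(ValueError, match="compound"):
            profile_pi(ds, d, "compound_poisson")


class TestBoundaryLrt:
    def test_point_mass_half_at_zero(self):
        assert boundary_lrt_pvalue(0.0) == 0.5

    def test_mixture_quantiles(self):
        # 0.5 * P(chi2_1 > 2.706) = 0.05 and 0.5 * P(chi2_1 > 3.841) = 0.025
        assert boundary_lrt_pvalue(2.706) == pytest.approx(0.05, abs=1e-3)
        assert boundary_lrt_pvalue(3.841) == pytest.approx(0.025, abs=1e-3)

    def test_negative_statistic_rejected(self):
        with pytest.raises(ValueError):
            boundary_lrt_pvalue(-0.1)


class TestEmpiricalBayes:
    def test_event_subjects_are_certain_movers(self):
        params = gamma_params(pi=0.3, disp=1.0)
        ds, _ = simulate_ms(params, 100, seed=37)
        d = build_designs(ds)
        fit = fit_ms(ds, d, "gamma", compute_cov=False)
        Eu, p_mover = empirical_bayes(fit, ds, d)
        y = ds.outcome
        from twopartlong.semicontinuous import _segment_starts
        S = np.add.reduceat(y, _segment_starts(ds.subject_codes))
        assert np.allclose(p_mover[S > 0], 1.0)
        assert np.all((p_mover >= 0) & (p_mover <= 1))

    def test_pi_zero_means_everyone_moves(self):
        params = gamma_params(pi=0.0, disp=1.0)
        ds, _ = simulate_ms(params, 50, seed=38)
        d = build_designs(ds)
        fit = fit_ms(ds, d, "gamma", pi_fixed=0.0, compute_cov=False)
        _, p_mover = empirical_bayes(fit, ds, d)
        assert np.allclose(p_mover, 1.0)

    def test_mover_probability_decreases_with_exposure(self):
        # an all-zero subject becomes a more plausible stayer the longer the
        # accumulated exposure
        probs = []
        for total_t in (0.5, 2.0, 8.0, 20.0):
            df = pd.DataFrame({"subject": [1, 1], "time": [total_t / 2, total_t],
                               "outcome": [0.0, 0.0],
                               "offset": [total_t / 2, total_t / 2]})
            ds = LongitudinalDataset(df)
            d = build_designs(ds)
            params = gamma_params(pi=0.3, disp=1.0)
            from twopartlong.moverstayer import _posterior_pieces
            p_mover, _, _, _ = _posterior_pieces(ds, d, params)
            probs.append(p_mover[0])
        assert np.all(np.diff(probs) < 0)


class TestEstimatorClass:
    def test_fit_gof_and_eb_through_estimator(self):
        from twopartlong.moverstayer import MoverStayerModel

        params = gamma_params(pi=0.3, disp=1.0, rate=0.8, beta=[0.3])
        ds, _ = simulate_ms(params, 150,
                            covariates={"a": lambda r, n: r.binomial(1, 0.4, n).astype(float)},
                            intensity_terms=("a",), seed=59)
        est = MoverStayerModel(intensity_terms=("a",), family="gamma")
        est.fit(ds)
        assert est.converged_
        assert 0.0 <= est.stayer_prob_ < 1.0
        Eu, pm = est.empirical_bayes()
        assert len(Eu) == est.n_subjects_
        table = est.gof()
        assert table.pearson >= 0.0
        assert est.get_params()["family"] == "gamma"


class TestPearsonGof:
    def test_statistic_zero_for_perfect_table(self):
        o = np.array([10.0, 5.0, 2.0])
        assert pearson_statistic(o, o.copy()) == 0.0

    def test_statistic_matches_formula(self):
        o = np.array([12.0, 6.0])
        e = np.array([10.0, 8.0])
        assert pearson_statistic(o, e) == pytest.approx(0.4 + 0.5)

    def test_expected_probabilities_normalised(self):
        params = gamma_params(pi=0.25, disp=1.2, rate=0.6)
        ds, _ = simulate_ms(params, 120, seed=43)
        d = build_designs(ds)
        fit = fit_ms(ds, d, "gamma", compute_cov=False)
        table = pearson_gof(fit, ds, d)
        # expected counts add up to the number of observations
        assert table.expected.sum() == pytest.approx(ds.n_obs, abs=1e-6)
        assert table.observed.sum() == ds.n_obs

    def test_model_correct_statistic_not_extreme(self):
        # fitting the generating model should not produce a wildly large
        # statistic; compare against a small parametric-bootstrap reference
        params = gamma_params(pi=0.25, disp=1.2, rate=0.6)
        ds, _ = simulate_ms(params, 150, seed=47)
        d = build_designs(ds)
        fit = fit_ms(ds, d, "gamma", compute_cov=False)
        stat = pearson_gof(fit, ds, d).pearson
        ref = []
        from twopartlong.moverstayer import params_from_fit
        fitted = params_from_fit(fit)
        for b in range(12):
            ds_b, _ = simulate_ms(fitted, 150, seed=100 + b)
            d_b = build_designs(ds_b)
            fit_b = fit_ms(ds_b, d_b, "gamma", compute_cov=False)
            ref.append(pearson_gof(fit_b, ds_b, d_b).pearson)
        assert stat < 3.0 * max(ref)
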