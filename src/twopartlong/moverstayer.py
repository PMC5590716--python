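"""Mover-stayer count models with two-part frailty distributions.

Counts of new events (e.g. newly damaged joints between clinic visits) are
modelled as Poisson with mean u_i * Lambda_ij, Lambda_ij = O_ij * lambda0 *
exp(X_ij beta), where the subject frailty U_i has a two-part law: a point
mass pi at zero ("stayers", who can never have an event) and a positive
density for "movers".  Three frailty families are supported -- unit-mean
gamma, unit-mean inverse Gaussian, and compound Poisson (whose atom at zero
ties pi to exp(-rate)) -- plus an observation-level gamma random effect that
turns the Poisson kernel into a negative binomial (the NB mover-stayer
class; dispersion 0 recovers the Poisson class).

The ever-event indicator c*_i = 1{sum_j y_ij > 0} is always derived from the
data: a subject with any event cannot be a stayer, so the stayer atom enters
only all-zero subjects' likelihood contributions.

Inference helpers: profile likelihood for pi with a boundary-adjusted
likelihood-ratio interval, the 50:50 point-mass/chi-square(1) boundary test,
empirical-Bayes frailty posteriors, and a Pearson goodness-of-fit table of
observed vs expected count increments.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln, roots_legendre
from scipy import stats

from .data import DesignMatrices, LongitudinalDataset
from .distributions import MoverStayerRE
from .estimation import FitResult, ParamTransform, maximize
from .quadrature import logsumexp
from .semicontinuous import _PanelEstimator, _segment_starts

logger = logging.getLogger(__name__)

__all__ = [
    "MoverStayerParams",
    "GofTable",
    "ms_subject_loglik",
    "loglik_ms",
    "nb_obs_kernel",
    "fit_ms",
    "profile_pi",
    "boundary_lrt_pvalue",
    "empirical_bayes",
    "pearson_gof",
    "pearson_statistic",
    "MoverStayerModel",
]


@dataclass(frozen=True)
class MoverStayerParams:
    """Baseline rate, regression coefficients, frailty law, NB dispersion.

    ``obs_dispersion`` is the observation-level gamma variance; 0 gives the
    Poisson mover-stayer class.  For the compound-Poisson family the baseline
    rate is constrained to one (the frailty mean rho/nu absorbs the scale).
    """

    baseline_rate: float
    beta: np.ndarray
    re: MoverStayerRE
    obs_dispersion: float = 0.0

    def __post_init__(self):
        if self.baseline_rate <= 0:
            raise ValueError("baseline_rate must be positive")
        if self.obs_dispersion < 0:
            raise ValueError("obs_dispersion must be nonnegative")
        if self.re.family == "compound_poisson" and not np.isclose(
            self.baseline_rate, 1.0
        ):
            raise ValueError(
                "compound_poisson frailty requires baseline_rate = 1 "
                "(identifiability: the frailty mean carries the scale)"
            )
        object.__setattr__(self, "beta", np.atleast_1d(np.asarray(self.beta, float)))


def _strip_intercept(designs: DesignMatrices):
    """The baseline rate plays the intercept's role; drop an all-ones column."""
    X = designs.X_intensity
    names = list(designs.intensity_names)
    if names and names[0] == "intercept":
        return X[:, 1:], names[1:]
    return X, names


def _log_lambda(ds, designs, params):
    X, _ = _strip_intercept(designs)
    eta = X @ params.beta if X.shape[1] else np.zeros(ds.n_obs)
    return np.log(params.baseline_rate) + designs.log_offset + eta


def nb_obs_kernel(y, u, lam, obs_dispersion):
    """Probability h(y | u; Lambda): Poisson mean u*Lambda mixed over a
    unit-mean gamma observation-level effect -> negative binomial.

    ``obs_dispersion = 0`` gives the Poisson pmf exactly.
    """
    return np.exp(_log_nb_kernel(np.asarray(y, float), np.asarray(u * lam, float),
                                 obs_dispersion))


def _log_nb_kernel(y, mean, obs_dispersion):
    """log h(y | mean): NB with unit-mean gamma mixing, Poisson at disp 0."""
    with np.errstate(divide="ignore"):
        logmean = np.where(mean > 0, np.log(np.maximum(mean, 1e-300)), -np.inf)
    if obs_dispersion == 0.0:
        out = y * logmean - mean - gammaln(y + 1.0)
        return np.where((mean == 0) & (y == 0), 0.0, out)
    r = 1.0 / obs_dispersion
    out = (gammaln(y + r) - gammaln(r) - gammaln(y + 1.0)
           + r * (np.log(r) - np.log(r + mean))
           + y * (logmean - np.log(r + mean)))
    return np.where((mean == 0) & (y == 0), 0.0, out)


# --------------------------------------------------------------------------
# frailty integrals

def _mover_integrals(ds, designs, params, n_quad=48, expand=8.0, extra_logu=0):
    """Per-subject log integrals over the positive frailty axis.

    Returns log of  I_i = int_0^inf prod_j h(y_ij | u; Lam_ij) g(u) du,
    where g is the *continuous* frailty density (unit mass for gamma/IG,
    mass 1 - exp(-rate) for compound Poisson).  ``extra_logu`` = k inserts a
    factor u^k (k = 1 gives the posterior-mean numerator).

    Gauss-Legendre on an adaptively located window of x = log u: a short
    Newton search finds the per-subject mode and curvature of the
    log-integrand and the window spans ``expand`` posterior sds.
    """
    y = ds.outcome
    loglam = _log_lambda(ds, designs, params)
    lam = np.exp(loglam)
    codes = ds.subject_codes
    starts = _segment_starts(codes)
    n = ds.n_subjects
    re = params.re

    def logint(x):
        # x: (n, m) values of log u; per-obs mean u_i * lam_ij
        u = np.exp(x)
        uu = u[codes]
        m = uu * lam[:, None]
        lk = _log_nb_kernel(y[:, None], m, params.obs_dispersion)
        per_sub = np.add.reduceat(lk, starts, axis=0)
        return per_sub + re.continuous_logpdf(u) + (1 + extra_logu) * x

    # mode search in x by vectorised Newton with finite differences
    x = np.zeros((n, 1))
    d = 1e-3
    for _ in range(40):
        f0, fp, fm = logint(x), logint(x + d), logint(x - d)
        g = (fp - fm) / (2 * d)
        H = (fp - 2 * f0 + fm) / d**2
        H = np.where(H < -1e-10, H, -1.0)
        step = np.clip(-g / H, -3.0, 3.0)
        x = x + step
        if np.max(np.abs(step)) < 1e-10:
            break
    f0 = logint(x)
    H = (logint(x + d) - 2 * f0 + logint(x - d)) / d**2
    H = np.where(H < -1e-10, H, -1.0)
    sd = 1.0 / np.sqrt(-H)
    nodes, logw = _window_nodes(logint, x, sd, f0, n_quad, expand)
    vals = logint(nodes)
    return logsumexp(logw + vals, axis=1)


def _window_nodes(logint, x, sd, f0, n_quad, expand=8.0, drop=35.0, max_panels=10):
    """Composite Gauss-Legendre nodes/log-weights on an adaptive window.

    The window around the per-subject mode is widened until the
    log-integrand has dropped ``drop`` below its peak on both sides (skewed
    posteriors -- e.g. all-zero subjects under a small-shape gamma frailty --
    have slow power-law tails that a Gaussian +/- k sd window would
    truncate), then split into panels of at most ~6 posterior sds so wide
    windows remain accurately resolved.
    """
    lo = x - expand * sd
    hi = x + expand * sd
    for _ in range(10):
        need = logint(lo) > f0 - drop
        if not np.any(need):
            break
        lo = np.where(need, lo - 5.0 * sd, lo)
    for _ in range(10):
        need = logint(hi) > f0 - drop
        if not np.any(need):
            break
        hi = np.where(need, hi + 5.0 * sd, hi)
    width = hi - lo
    n_panels = int(min(max_panels, max(2, np.ceil(np.max(width / sd) / 6.0))))
    z, w = roots_legendre(max(8, n_quad // 2))
    edges = lo + width * np.linspace(0.0, 1.0, n_panels + 1)[None, :]
    nodes, logws = [], []
    for k in range(n_panels):
        a, b = edges[:, k:k + 1], edges[:, k + 1:k + 2]
        half = 0.5 * (b - a)
        nodes.append(0.5 * (a + b) + half * z[None, :])
        logws.append(np.log(w)[None, :] + np.log(half))
    return np.concatenate(nodes, axis=1), np.concatenate(logws, axis=1)


def loglik_ms(ds, designs, params: MoverStayerParams, n_quad=48,
              per_subject=False, use_closed_form=True):
    """Marginal log-likelihood of the (NB) mover-stayer model.

    For the gamma frailty without observation-level effects the subject
    integral is a closed-form negative-binomial kernel; other cases use
    adaptive Gauss-Legendre quadrature on the log-frailty axis.  The stayer
    atom contributes only for subjects with no events.
    """
    y = ds.outcome
    codes = ds.subject_codes
    starts = _segment_starts(codes)
    S = np.add.reduceat(y, starts)
    ever = S > 0
    re = params.re
    pi = re.stayer_prob

    if re.family == "gamma" and params.obs_dispersion == 0.0 and use_closed_form:
        loglam = _log_lambda(ds, designs, params)
        lam = np.exp(loglam)
        T = np.add.reduceat(lam, starts)
        const = np.add.reduceat(y * loglam - gammaln(y + 1.0), starts)
        r = 1.0 / re.gamma_dispersion
        logI = (const + r * np.log(r) - gammaln(r)
                + gammaln(r + S) - (r + S) * np.log(r + T))
    else:
        logI = _mover_integrals(ds, designs, params, n_quad)

    if re.family == "compound_poisson":
        # continuous part already has mass 1 - pi; atom enters directly
        ll = np.where(ever, logI, np.logaddexp(np.log(pi), logI))
    else:
        log1mpi = np.log1p(-pi)
        if pi > 0:
            ll = np.where(ever, log1mpi + logI,
                          np.logaddexp(np.log(pi), log1mpi + logI))
        else:
            ll = logI
    return ll if per_subject else float(np.sum(ll))


def ms_subject_loglik(subject_df, designs_builder, params: MoverStayerParams,
                      n_quad=48):
    """Marginal log-likelihood contribution of a single subject.

    ``subject_df`` is that subject's rows; ``designs_builder`` maps a
    one-subject dataset to its DesignMatrices (typically
    ``lambda d: build_designs(d, intensity_terms=...)``).
    """
    ds = LongitudinalDataset(subject_df)
    designs = designs_builder(ds)
    return float(loglik_ms(ds, designs, params, n_quad))


# --------------------------------------------------------------------------
# fitting

_FAMILY_PARAM = {
    "gamma": ("gamma_dispersion", "log"),
    "inverse_gaussian": ("ig_shape", "log"),
}


def _ms_paramvec(designs, family, obs_level, pi_fixed):
    _, xnames = _strip_intercept(designs)
    names, links = [], []
    if family != "compound_poisson":
        names.append("baseline_rate")
        links.append("log")
    names += [f"rate:{n}" for n in xnames]
    links += ["identity"] * len(xnames)
    if family == "compound_poisson":
        names += ["cp_rate", "cp_summand_rate"]
        links += ["log", "log"]
    else:
        pname, plink = _FAMILY_PARAM[family]
        names.append(pname)
        links.append(plink)
        if pi_fixed is None:
            names.append("stayer_prob")
            links.append("logit")
    if obs_level:
        names.append("obs_dispersion")
        links.append("log")
    return tuple(names), tuple(links)


def _ms_unpack(nat, names, family, obs_level, pi_fixed):
    d = dict(zip(names, nat))
    obs_disp = d.get("obs_dispersion", 0.0)
    nb = len([n for n in names if n.startswith("rate:")])
    beta = np.array([d[n] for n in names if n.startswith("rate:")])
    if family == "compound_poisson":
        re = MoverStayerRE("compound_poisson", cp_rate=d["cp_rate"],
                           cp_summand_rate=d["cp_summand_rate"])
        return MoverStayerParams(1.0, beta, re, obs_disp)
    pi = pi_fixed if pi_fixed is not None else d.get("stayer_prob", 0.0)
    if family == "gamma":
        re = MoverStayerRE("gamma", stayer_prob=pi,
                           gamma_dispersion=d["gamma_dispersion"])
    else:
        re = MoverStayerRE("inverse_gaussian", stayer_prob=pi,
                           ig_shape=d["ig_shape"])
    return MoverStayerParams(d["baseline_rate"], beta, re, obs_disp)


def fit_ms(ds, designs, family="gamma", obs_level=False, init=None,
           pi_fixed=None, n_quad=48, compute_cov=True, robust=False) -> FitResult:
    """ML fit of a Poisson or negative-binomial mover-stayer model.

    ``family`` is the frailty law ('gamma', 'inverse_gaussian',
    'compound_poisson'); ``obs_level=True`` adds the observation-level gamma
    dispersion (NB class).  The stayer probability is a single constant pi
    (covariate-dependent pi is out of scope); for the compound-Poisson family
    pi is not free -- it always equals exp(-cp_rate).  An estimate of pi at
    the boundary is flagged; use :func:`profile_pi` to examine the likelihood
    there.
    """
    ds.require_counts()
    names, links = _ms_paramvec(designs, family, obs_level, pi_fixed)
    pt = ParamTransform(names, links)
    if init is None:
        rate0 = max(float(np.sum(ds.outcome) / np.sum(ds.offset)), 1e-3)
        d0 = {"baseline_rate": rate0, "cp_rate": 1.0,
              "cp_summand_rate": max(1.0 / rate0, 1e-2), "gamma_dispersion": 1.0,
              "ig_shape": 1.0, "stayer_prob": 0.2, "obs_dispersion": 0.5}
        nat = np.array([d0.get(n, 0.0) for n in names])
    else:
        nat = np.asarray(init, float)
    x0 = pt.to_unconstrained(nat)

    def persub(x):
        return loglik_ms(ds, designs, _ms_unpack(pt.to_natural(x), names, family,
                                                 obs_level, pi_fixed),
                         n_quad, per_subject=True)

    fit = maximize(lambda x: float(np.sum(persub(x))), x0, pt, ds.n_subjects,
                   ds.n_obs, quad_order=n_quad, per_subject_loglik=persub,
                   robust=robust, compute_cov=compute_cov)
    fit.extra["model"] = "mover_stayer"
    fit.extra["family"] = family
    fit.extra["obs_level"] = bool(obs_level)
    if pi_fixed is not None:
        fit.extra["pi_fixed"] = float(pi_fixed)
    params = _ms_unpack(fit.estimates, names, family, obs_level, pi_fixed)
    fit.extra["stayer_prob"] = float(params.re.stayer_prob)
    if family == "compound_poisson":
        fit.extra["stayer_prob_identity"] = "exp(-cp_rate)"
    elif pi_fixed is None and params.re.stayer_prob < 0.01:
        fit.extra["pi_boundary"] = True
        fit.message = (fit.message + " | stayer probability estimated at the "
                       "boundary; inspect profile_pi for the profile likelihood")
    return fit


# --------------------------------------------------------------------------
# profile likelihood and boundary inference

def boundary_lrt_pvalue(lr_stat: float) -> float:
    """P-value of the boundary LRT for H0: pi = 0.

    The null distribution is a 50:50 mixture of a point mass at zero and
    chi-square(1): p = 0.5 P(chi2_1 > T) for T > 0 and 0.5 at T = 0.
    """
    if lr_stat < 0:
        raise ValueError("likelihood-ratio statistic must be nonnegative")
    if lr_stat == 0:
        return 0.5
    return float(0.5 * stats.chi2.sf(lr_stat, 1))


# 95% critical value of the 50:50 mixture: P(T > c) = 0.05 <=> chi2_1 at 0.10
BOUNDARY_CRIT_95 = float(stats.chi2.isf(0.10, 1))  # 2.706


def profile_pi(ds, designs, family="gamma", obs_level=False, pi_grid=None,
               n_quad=48, level=0.95):
    """Profile log-likelihood of the stayer probability pi.

    At each grid value all remaining parameters are re-maximised (warm
    started along the grid).  The likelihood-ratio confidence set uses the
    boundary-adjusted critical value (2.706 at the 95% level).  Only for the
    gamma / inverse-Gaussian families, where pi is a free parameter.
    """
    if family == "compound_poisson":
        raise ValueError("pi is not a free parameter for the compound-Poisson "
                         "family (pi = exp(-cp_rate)); profile cp_rate instead")
    if pi_grid is None:
        pi_grid = np.linspace(0.0, 0.95, 41)
    pi_grid = np.asarray(pi_grid, float)
    if np.any((pi_grid < 0) | (pi_grid >= 1)):
        raise ValueError("pi grid must lie in [0, 1)")
    lls = np.full(len(pi_grid), np.nan)
    init = None
    for k, pi in enumerate(pi_grid):
        try:
            f = fit_ms(ds, designs, family, obs_level, init=init, pi_fixed=float(pi),
                       n_quad=n_quad, compute_cov=False)
            lls[k] = f.loglik
            init = f.estimates
        except Exception as exc:  # pragma: no cover - inner non-convergence
            logger.warning("profile point pi=%.3f failed: %s", pi, exc)
    ok = np.isfinite(lls)
    kmax = int(np.nanargmax(lls))
    llmax = float(lls[kmax])
    crit = float(stats.chi2.isf(2 * (1 - level), 1))  # mixture quantile
    inside = ok & (2.0 * (llmax - lls) <= crit)
    ci = (float(pi_grid[inside].min()), float(pi_grid[inside].max()))
    return {
        "pi_grid": pi_grid,
        "profile_loglik": lls,
        "pi_hat": float(pi_grid[kmax]),
        "loglik_max": llmax,
        "ci": ci,
        "critical_value": crit,
        "monotone_decreasing": bool(np.all(np.diff(lls[ok]) <= 1e-6)),
    }


# --------------------------------------------------------------------------
# empirical Bayes and goodness of fit

def _posterior_pieces(ds, designs, params, n_quad=48):
    """Per-subject stayer/mover posterior masses and mover posterior of u."""
    y = ds.outcome
    starts = _segment_starts(ds.subject_codes)
    S = np.add.reduceat(y, starts)
    ever = S > 0
    pi = params.re.stayer_prob
    logI0 = _mover_integrals(ds, designs, params, n_quad, extra_logu=0)
    logI1 = _mover_integrals(ds, designs, params, n_quad, extra_logu=1)
    if params.re.family == "compound_poisson":
        log_mover = logI0
    else:
        log_mover = np.log1p(-pi) + logI0
    with np.errstate(divide="ignore"):
        log_stayer = np.where(ever, -np.inf, np.log(pi) if pi > 0 else -np.inf)
    log_total = np.logaddexp(log_mover, log_stayer)
    p_mover = np.exp(log_mover - log_total)
    # posterior mean of u: stayers contribute 0
    Eu = np.exp(logI1 - logI0) * p_mover
    return p_mover, Eu, logI0, log_total


def empirical_bayes(fit: FitResult, ds, designs, n_quad=48):
    """Empirical-Bayes posterior mean frailty and mover probability.

    Subjects with any event have mover probability one; for all-zero
    subjects the mover probability decreases with accumulated exposure.
    """
    params = params_from_fit(fit)
    p_mover, Eu, _, _ = _posterior_pieces(ds, designs, params, n_quad)
    return Eu, p_mover


def params_from_fit(fit: FitResult) -> MoverStayerParams:
    names = list(fit.names)
    family = fit.extra["family"]
    obs_level = fit.extra["obs_level"]
    return _ms_unpack(fit.estimates, names, family, obs_level,
                      fit.extra.get("pi_fixed"))


def pearson_statistic(observed, expected) -> float:
    """Pearson X^2 = sum_y (o(y) - e(y))^2 / e(y) over count categories."""
    o = np.asarray(observed, float)
    e = np.asarray(expected, float)
    if np.any(e <= 0):
        raise ValueError("expected counts must be positive")
    return float(np.sum((o - e) ** 2 / e))


@dataclass
class GofTable:
    """Observed vs expected count-increment frequencies and Pearson X^2."""

    categories: tuple
    observed: np.ndarray
    expected: np.ndarray
    pearson: float
    display_categories: tuple = ()
    display_observed: np.ndarray | None = None
    display_expected: np.ndarray | None = None

    def render(self) -> str:
        cats = self.display_categories or self.categories
        obs = self.display_observed if self.display_observed is not None else self.observed
        exp = self.display_expected if self.display_expected is not None else self.expected
        lines = [f"{'increment':<26}{'observed':>10}{'expected':>12}"]
        for c, o, e in zip(cats, obs, exp):
            lines.append(f"{str(c):<26}{o:>10.0f}{e:>12.2f}")
        lines.append(f"{'total':<26}{obs.sum():>10.0f}{exp.sum():>12.2f}")
        lines.append(f"Pearson statistic: {self.pearson:.2f}")
        return "\n".join(lines)


def pearson_gof(fit: FitResult, ds, designs, max_count=8, n_quad=48) -> GofTable:
    """Observed vs model-expected increments of the count outcome.

    For each observation the expected category probabilities e_ij(y) mix the
    stayer atom (degenerate at zero) with the mover predictive distribution,
    integrating the Poisson/NB kernel over the full empirical-Bayes posterior
    of the frailty given all of the subject's data.  The display table uses
    the categories (0 without / 0 with previous events, 1, 2, 3, 4, >4); the
    Pearson statistic sum_y (o(y) - e(y))^2 / e(y) expands >4 into 4..8 and
    >8.  A statistic category with zero expected mass is merged with its
    neighbour (logged).
    """
    params = params_from_fit(fit)
    y = ds.outcome
    loglam = _log_lambda(ds, designs, params)
    lam = np.exp(loglam)
    codes = ds.subject_codes
    starts = _segment_starts(codes)
    n = ds.n_subjects
    pi = params.re.stayer_prob
    re = params.re

    # posterior over u per subject on a quadrature grid (mover branch)
    # reuse the adaptive window construction from _mover_integrals
    def logint(x, extra=0):
        u = np.exp(x)
        uu = u[codes]
        m = uu * lam[:, None]
        lk = _log_nb_kernel(y[:, None], m, params.obs_dispersion)
        per_sub = np.add.reduceat(lk, starts, axis=0)
        return per_sub + re.continuous_logpdf(u) + (1 + extra) * x

    x = np.zeros((n, 1))
    d = 1e-3
    for _ in range(40):
        f0, fp, fm = logint(x), logint(x + d), logint(x - d)
        g = (fp - fm) / (2 * d)
        H = (fp - 2 * f0 + fm) / d**2
        H = np.where(H < -1e-10, H, -1.0)
        step = np.clip(-g / H, -3.0, 3.0)
        x = x + step
        if np.max(np.abs(step)) < 1e-10:
            break
    f0 = logint(x)
    H = (logint(x + d) - 2 * f0 + logint(x - d)) / d**2
    H = np.where(H < -1e-10, H, -1.0)
    sd = 1.0 / np.sqrt(-H)
    nodes, logw = _window_nodes(logint, x, sd, f0, n_quad)
    logvals = logw + logint(nodes)
    logI0 = logsumexp(logvals, axis=1)
    post_w = np.exp(logvals - logI0[:, None])  # (n, m) posterior weights of u
    u_nodes = np.exp(nodes)

    S = np.add.reduceat(y, starts)
    ever = S > 0
    if re.family == "compound_poisson":
        log_mover = logI0
    else:
        log_mover = np.log1p(-pi) + logI0
    log_stayer = np.where(ever, -np.inf, np.log(pi) if pi > 0 else -np.inf)
    log_total = np.logaddexp(log_mover, log_stayer)
    p_mover = np.exp(log_mover - log_total)

    yvals = np.arange(0, max_count + 1)
    # expected prob of each y value per observation
    probs = np.empty((ds.n_obs, len(yvals) + 1))
    mean_obs = u_nodes[codes] * lam[:, None]  # (n_obs, m)
    pm_obs = p_mover[codes]
    for k, yy in enumerate(yvals):
        hk = np.exp(_log_nb_kernel(float(yy), mean_obs, params.obs_dispersion))
        mover_prob = np.sum(post_w[codes] * hk, axis=1)
        probs[:, k] = pm_obs * mover_prob + (1 - pm_obs) * (1.0 if yy == 0 else 0.0)
    probs[:, -1] = np.maximum(1.0 - probs[:, :-1].sum(axis=1), 0.0)  # > max_count

    # previous-damage split for the zero category
    cum_prev = np.zeros(ds.n_obs)
    ycum = np.cumsum(y)
    for s, e in zip(starts, np.append(starts[1:], ds.n_obs)):
        cs = np.concatenate([[0.0], np.cumsum(y[s:e - 1])])
        cum_prev[s:e] = cs
    no_prev = cum_prev == 0

    stat_labels = (["0 without previous events", "0 with previous events"]
                   + [str(v) for v in yvals[1:]] + [f">{max_count}"])
    e_stat = np.concatenate([
        [probs[no_prev, 0].sum(), probs[~no_prev, 0].sum()],
        probs[:, 1:].sum(axis=0),
    ])
    o_stat = np.concatenate([
        [float(((y == 0) & no_prev).sum()), float(((y == 0) & ~no_prev).sum())],
        [float((y == v).sum()) for v in yvals[1:]],
        [float((y > max_count).sum())],
    ])
    # merge zero-expected categories with their left neighbour
    keep_l, keep_o, keep_e = [], [], []
    for lbl, o, e in zip(stat_labels, o_stat, e_stat):
        if e <= 0 and keep_e:
            logger.info("merging zero-expected category %s with neighbour", lbl)
            keep_o[-1] += o
            keep_e[-1] += e
        else:
            keep_l.append(lbl)
            keep_o.append(o)
            keep_e.append(e)
    o_stat = np.array(keep_o)
    e_stat = np.array(keep_e)
    pearson = pearson_statistic(o_stat, e_stat)

    # display table: 0-split, 1..3, 4, >4
    disp_labels = (["0 without previous events", "0 with previous events",
                    "1", "2", "3", "4", ">4"])
    disp_e = np.concatenate([
        [probs[no_prev, 0].sum(), probs[~no_prev, 0].sum()],
        probs[:, 1:5].sum(axis=0) if max_count >= 4 else probs[:, 1:].sum(axis=0),
        [probs[:, 5:].sum()],
    ])
    disp_o = np.concatenate([
        [float(((y == 0) & no_prev).sum()), float(((y == 0) & ~no_prev).sum())],
        [float((y == v).sum()) for v in (1, 2, 3, 4)],
        [float((y > 4).sum())],
    ])
    return GofTable(
        categories=tuple(keep_l), observed=o_stat, expected=e_stat,
        pearson=pearson, display_categories=tuple(disp_labels),
        display_observed=disp_o, display_expected=disp_e,
    )


# --------------------------------------------------------------------------
# estimator

class MoverStayerModel(_PanelEstimator):
    """Mover-stayer count model as a scikit-learn style estimator.

    Parameters
    ----------
    intensity_terms : covariate names for the event-rate predictor (the
        baseline rate lambda0 plays the intercept's role).
    family : frailty law, 'gamma' | 'inverse_gaussian' | 'compound_poisson'.
    obs_level : add observation-level gamma dispersion (NB class).
    use_gap_offsets : recompute offsets as inter-visit gaps before fitting.
    """

    def __init__(self, intensity_terms=None, family="gamma", obs_level=False,
                 pi_fixed=None, n_quad=48, use_gap_offsets=False):
        self.intensity_terms = intensity_terms
        self.family = family
        self.obs_level = obs_level
        self.pi_fixed = pi_fixed
        self.n_quad = n_quad
        self.use_gap_offsets = use_gap_offsets
        self.binary_terms = None
        self.interactions = None

    def fit(self, X, y=None):
        from .data import inter_visit_offsets

        ds = self._as_dataset(X)
        if self.use_gap_offsets:
            ds = inter_visit_offsets(ds)
        designs = self._designs(ds)
        fit = fit_ms(ds, designs, self.family, self.obs_level,
                     pi_fixed=self.pi_fixed, n_quad=self.n_quad)
        self.designs_ = designs
        self.params_ = params_from_fit(fit)
        self.stayer_prob_ = fit.extra["stayer_prob"]
        self._ds = ds
        return self._finalize(ds, fit)

    def _per_subject_loglik(self, ds):
        return loglik_ms(ds, self._designs(ds), self.params_, self.n_quad,
                         per_subject=True)

    def empirical_bayes(self):
        return empirical_bayes(self.result_, self._ds, self.designs_, self.n_quad)

    def gof(self, max_count=8) -> GofTable:
        return pearson_gof(self.result_, self._ds, self.designs_, max_count,
                           self.n_quad)

    def profile_pi(self, pi_grid=None):
        return profile_pi(self._ds, self.designs_, self.family, self.obs_level,
                          pi_grid, self.n_quad)
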