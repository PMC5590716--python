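"""Zero-inflated and hurdle count models with correlated random intercepts.

Three families:

* ``ZIPRandomInterceptModel`` -- zero-inflated Poisson: a partially latent
  Bernoulli Z_ij mixes a structural zero with a full Poisson count whose mean
  is conditional on a subject random intercept; the occurrence and count
  intercepts (U_i, V_i) may be correlated.
* ``MarginalizedZIPModel`` -- instead of the latent-class Poisson mean, the
  subject-specific *overall* mean nu_ij = E[Y_ij | X, W_i] is modelled
  log-linearly, so each alpha_k is directly a subject-specific log incidence
  density ratio (IDR).  The latent-class mean is recovered through the
  matching term delta_ij and never stored.  Robust (sandwich) standard errors
  are reported by default.
* ``HurdleModel`` -- all zeros come from the Bernoulli part; positives follow
  a zero-truncated Poisson.

Z_ij is partially latent for the zero-inflated families: Y_ij > 0 forces
Z_ij = 1 but a zero observation leaves Z_ij unknown, and the likelihood sums
over both possibilities.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln
from scipy import stats

from .data import DesignMatrices, LongitudinalDataset, build_designs
from .distributions import BivariateNormalRE
from .estimation import FitResult, ParamTransform, maximize
from .quadrature import log_marginal_subjects_2d
from .semicontinuous import _PanelEstimator, _init_binary, _log_sigmoid, _segment_starts

__all__ = [
    "ZipParams",
    "MarginalizedZipParams",
    "zip_obs_logpmf",
    "hurdle_logpmf",
    "mzip_delta",
    "loglik_zip",
    "loglik_mzip",
    "loglik_hurdle",
    "fit_zip",
    "fit_mzip",
    "fit_hurdle",
    "idr_report",
    "derived_re_correlation",
    "percent_reduction",
    "ZIPRandomInterceptModel",
    "MarginalizedZIPModel",
    "HurdleModel",
]


@dataclass(frozen=True)
class ZipParams:
    """ZIP with random intercepts: binary-part theta, Poisson-part beta."""

    theta: np.ndarray
    beta: np.ndarray
    re: BivariateNormalRE

    def __post_init__(self):
        object.__setattr__(self, "theta", np.atleast_1d(np.asarray(self.theta, float)))
        object.__setattr__(self, "beta", np.atleast_1d(np.asarray(self.beta, float)))


@dataclass(frozen=True)
class MarginalizedZipParams:
    """Marginalised ZIP: overall-mean coefficients alpha replace beta."""

    theta: np.ndarray
    alpha: np.ndarray
    re: BivariateNormalRE

    def __post_init__(self):
        object.__setattr__(self, "theta", np.atleast_1d(np.asarray(self.theta, float)))
        object.__setattr__(self, "alpha", np.atleast_1d(np.asarray(self.alpha, float)))


# --------------------------------------------------------------------------
# observation-level pmfs

def _poisson_logpmf(y, logmu):
    return y * logmu - np.exp(logmu) - gammaln(y + 1.0)


def _zip_logpmf_core(y, logit_p, logmu):
    """log[(1-p) 1{y=0} + p Poisson(y; mu)] with p = sigmoid(logit_p)."""
    log_p = _log_sigmoid(logit_p)
    log_1mp = _log_sigmoid(-logit_p)
    pois = _poisson_logpmf(y, logmu)
    zero = np.logaddexp(log_1mp, log_p + pois)
    return np.where(y == 0, zero, log_p + pois)


def zip_obs_logpmf(y, p_occ, mu):
    """Log pmf of a single zero-inflated Poisson observation.

    ``p_occ`` is the probability of the non-structural-zero class and ``mu``
    the Poisson mean of that class; assembled in the log domain.
    """
    y = np.asarray(y, dtype=float)
    p_occ = np.asarray(p_occ, dtype=float)
    mu = np.asarray(mu, dtype=float)
    logit_p = np.log(p_occ) - np.log1p(-p_occ)
    return _zip_logpmf_core(y, logit_p, np.log(mu))


def hurdle_logpmf(y, p_pos, mu):
    """Log pmf of a hurdle (zero-altered) Poisson observation.

    Zeros come only from the Bernoulli part (prob 1 - p_pos); positives
    follow a Poisson truncated at zero.
    """
    y = np.asarray(y, dtype=float)
    p_pos = np.asarray(p_pos, dtype=float)
    mu = np.asarray(mu, dtype=float)
    with np.errstate(divide="ignore"):
        log_p = np.log(p_pos)
        log_1mp = np.log1p(-p_pos)
    # log(1 - e^{-mu}), stable for small mu
    log_trunc = np.log(-np.expm1(-mu))
    pos = log_p + _poisson_logpmf(y, np.log(mu)) - log_trunc
    return np.where(y == 0, log_1mp, pos)


def mzip_delta(x, x_star, theta, alpha, u, w, log_offset=0.0):
    """Matching term delta_ij of the marginalised ZIP.

    delta = log O + log{1 + exp(-(X theta + u))} + X* alpha + w, so that the
    latent-class Poisson mean exp(delta) satisfies
    (1 - Pr(Z=0 | u)) exp(delta) = exp(X* alpha + log O + w).
    """
    t = np.dot(np.atleast_1d(x), np.atleast_1d(theta)) + u
    return (log_offset + np.logaddexp(0.0, -t)
            + np.dot(np.atleast_1d(x_star), np.atleast_1d(alpha)) + w)


# --------------------------------------------------------------------------
# marginal log-likelihoods

def _count_pieces(ds: LongitudinalDataset, designs: DesignMatrices):
    ds.require_counts()
    y = ds.outcome
    codes = ds.subject_codes
    return y, codes, _segment_starts(codes)


def loglik_zip(ds, designs, params: ZipParams, rule=20, adaptive=True,
               per_subject=False, offset_in_logit=False):
    """Marginal log-likelihood of the ZIP model with correlated intercepts.

    Offsets enter the count part only unless ``offset_in_logit`` is set.
    """
    y, codes, starts = _count_pieces(ds, designs)
    eta_b = designs.X_binary @ params.theta
    if offset_in_logit:
        eta_b = eta_b + designs.log_offset
    eta_c = designs.X_intensity @ params.beta + designs.log_offset

    def cond(u, v):
        lp = eta_b[:, None] + u[codes]
        logmu = eta_c[:, None] + v[codes]
        return np.add.reduceat(_zip_logpmf_core(y[:, None], lp, logmu), starts, axis=0)

    ll = log_marginal_subjects_2d(cond, ds.n_subjects, params.re.cov, rule, adaptive)
    return ll if per_subject else float(np.sum(ll))


def loglik_mzip(ds, designs, params: MarginalizedZipParams, rule=20, adaptive=True,
                per_subject=False, offset_in_logit=False):
    """Marginal log-likelihood of the marginalised ZIP model.

    Identical mixture structure to the ZIP, but the latent-class mean is
    exp(delta_ij) with delta built from the overall-mean predictor.
    """
    y, codes, starts = _count_pieces(ds, designs)
    eta_b = designs.X_binary @ params.theta
    if offset_in_logit:
        eta_b = eta_b + designs.log_offset
    eta_a = designs.X_intensity @ params.alpha + designs.log_offset

    def cond(u, w):
        t = eta_b[:, None] + u[codes]
        delta = np.logaddexp(0.0, -t) + eta_a[:, None] + w[codes]
        return np.add.reduceat(_zip_logpmf_core(y[:, None], t, delta), starts, axis=0)

    ll = log_marginal_subjects_2d(cond, ds.n_subjects, params.re.cov, rule, adaptive)
    return ll if per_subject else float(np.sum(ll))


def loglik_hurdle(ds, designs, params: ZipParams, rule=20, adaptive=True,
                  per_subject=False):
    """Marginal log-likelihood of the hurdle model with normal intercepts."""
    y, codes, starts = _count_pieces(ds, designs)
    z = (y > 0)
    eta_b = designs.X_binary @ params.theta
    eta_c = designs.X_intensity @ params.beta + designs.log_offset

    def cond(u, v):
        lp = eta_b[:, None] + u[codes]
        logmu = eta_c[:, None] + v[codes]
        mu = np.exp(logmu)
        pos = (_log_sigmoid(lp) + _poisson_logpmf(y[:, None], logmu)
               - np.log(-np.expm1(-mu)))
        vals = np.where(z[:, None], pos, _log_sigmoid(-lp))
        return np.add.reduceat(vals, starts, axis=0)

    ll = log_marginal_subjects_2d(cond, ds.n_subjects, params.re.cov, rule, adaptive)
    return ll if per_subject else float(np.sum(ll))


# --------------------------------------------------------------------------
# fitting

def _count_init(ds, designs):
    y = ds.outcome
    z = (y > 0).astype(float)
    th0 = _init_binary(designs.X_binary, z)
    pos = y > 0
    # crude Poisson start: intercept at the log mean rate of positives
    b0 = np.zeros(designs.p)
    rate = max(np.mean(y[pos] / ds.offset[pos]) if pos.any() else 0.5, 1e-3)
    b0[0] = np.log(rate)
    return th0, b0


def _fit_count_family(ds, designs, loglik_fn, params_cls, kind, quad_order,
                      rho_fixed, robust, compute_cov, init=None):
    q, p = designs.q, designs.p
    part2 = "alpha" if kind == "mzip" else "count"
    names = ([f"binary:{n}" for n in designs.binary_names]
             + [f"{part2}:{n}" for n in designs.intensity_names]
             + ["var_u", "var_v"]
             + ([] if rho_fixed is not None else ["rho"]))
    links = (["identity"] * (q + p) + ["log", "log"]
             + ([] if rho_fixed is not None else ["atanh"]))
    pt = ParamTransform(tuple(names), tuple(links))
    if init is None:
        th0, b0 = _count_init(ds, designs)
        nat = np.concatenate([th0, b0, [0.5, 0.5],
                              [] if rho_fixed is not None else [0.0]])
    else:
        nat = np.asarray(init, float)
    if rho_fixed is None:
        nat[-1] = np.clip(nat[-1], -0.99, 0.99)
    x0 = pt.to_unconstrained(nat)

    def unpack(x):
        natv = pt.to_natural(x)
        rho = rho_fixed if rho_fixed is not None else natv[q + p + 2]
        re = BivariateNormalRE(natv[q + p], natv[q + p + 1], float(rho))
        return params_cls(natv[:q], natv[q:q + p], re)

    def persub(x):
        return loglik_fn(ds, designs, unpack(x), quad_order, True, per_subject=True)

    fit = maximize(lambda x: float(np.sum(persub(x))), x0, pt, ds.n_subjects,
                   ds.n_obs, quad_order, per_subject_loglik=persub, robust=robust,
                   compute_cov=compute_cov)
    fit.extra["model"] = kind
    fit.extra["binary_names"] = list(designs.binary_names)
    fit.extra["intensity_names"] = list(designs.intensity_names)
    if rho_fixed is not None:
        fit.extra["rho_fixed"] = float(rho_fixed)
    # variance block on the reporting scale: sd's plus covariance and rho
    vu, vv = fit["var_u"], fit["var_v"]
    rho = float(rho_fixed) if rho_fixed is not None else fit["rho"]
    fit.extra["variance_block"] = {
        "sd_u": float(np.sqrt(vu)),
        "sd_v": float(np.sqrt(vv)),
        "cov_uv": float(rho * np.sqrt(vu * vv)),
        "rho": float(rho),
    }
    return fit


def fit_zip(ds, designs, quad_order=20, rho_fixed=None, robust=False,
            compute_cov=True, init=None) -> FitResult:
    """ML fit of the ZIP model with correlated normal random intercepts."""
    return _fit_count_family(ds, designs, loglik_zip, ZipParams, "zip",
                             quad_order, rho_fixed, robust, compute_cov, init)


def fit_mzip(ds, designs, quad_order=20, rho_fixed=None, robust=True,
             compute_cov=True, init=None) -> FitResult:
    """ML fit of the marginalised ZIP; sandwich SEs reported by default.

    Each alpha_k is a subject-specific log-IDR: exp(alpha_k) multiplies the
    overall mean per unit increase of the covariate.
    """
    return _fit_count_family(ds, designs, loglik_mzip, MarginalizedZipParams,
                             "mzip", quad_order, rho_fixed, robust, compute_cov,
                             init)


def fit_hurdle(ds, designs, quad_order=20, rho_fixed=None, robust=False,
               compute_cov=True, init=None) -> FitResult:
    """ML fit of the hurdle (truncated-Poisson) model with normal intercepts."""
    return _fit_count_family(ds, designs, loglik_hurdle, ZipParams, "hurdle",
                             quad_order, rho_fixed, robust, compute_cov, init)


def idr_report(fit: FitResult, which, level: float = 0.95, robust: bool = True):
    """Incidence density ratio exp(alpha_k) with a Wald CI.

    ``which`` is a coefficient name (with or without the ``alpha:`` prefix)
    or integer index into the overall-mean block.  Robust SEs are used when
    available; otherwise model-based SEs with a warning.
    """
    import warnings

    names = list(fit.names)
    alpha_idx = [i for i, n in enumerate(names)
                 if n.startswith("alpha:") or n.startswith("count:")]
    if isinstance(which, int):
        i = alpha_idx[which]
    else:
        cands = [i for i in alpha_idx if names[i].split(":", 1)[1] == which
                 or names[i] == which]
        if not cands:
            raise KeyError(f"no overall-mean coefficient named {which!r}")
        i = cands[0]
    cov = fit.cov_robust
    if robust and cov is None:
        warnings.warn("no robust covariance available; using model-based SEs")
    if not robust or cov is None:
        cov = fit.cov_model
    se = float(np.sqrt(max(cov[i, i], 0.0)))
    z = stats.norm.ppf(0.5 * (1 + level))
    a = float(fit.estimates[i])
    return {
        "coefficient": names[i],
        "log_idr": a,
        "se": se,
        "idr": float(np.exp(a)),
        "ci": (float(np.exp(a - z * se)), float(np.exp(a + z * se))),
    }


def derived_re_correlation(var_u: float, cov_uv: float, var_v: float) -> float:
    """Random-intercept correlation implied by a variance block
    (var_u, cov_uv, var_v): rho = cov_uv / sqrt(var_u * var_v)."""
    if var_u <= 0 or var_v <= 0:
        raise ValueError("variances must be positive")
    return float(cov_uv / np.sqrt(var_u * var_v))


def percent_reduction(log_idr: float) -> float:
    """Percent reduction in the mean implied by a log-IDR:
    100 (1 - exp(log_idr))."""
    return float(100.0 * (1.0 - np.exp(log_idr)))


# --------------------------------------------------------------------------
# estimators

class _CountEstimator(_PanelEstimator):
    _kind = None

    def __init__(self, binary_terms=None, intensity_terms=None, interactions=None,
                 quad_order=20, rho_fixed=None, robust=False):
        self.binary_terms = binary_terms
        self.intensity_terms = intensity_terms
        self.interactions = interactions
        self.quad_order = quad_order
        self.rho_fixed = rho_fixed
        self.robust = robust

    _fitters = {}

    def fit(self, X, y=None):
        ds = self._as_dataset(X)
        designs = self._designs(ds)
        fitter = {"zip": fit_zip, "mzip": fit_mzip, "hurdle": fit_hurdle}[self._kind]
        fit = fitter(ds, designs, self.quad_order, self.rho_fixed,
                     robust=self.robust)
        self.designs_ = designs
        q, p = designs.q, designs.p
        rho = fit.extra.get("rho_fixed", fit.estimates[q + p + 2]
                            if "rho" in fit.names else 0.0)
        re = BivariateNormalRE(fit["var_u"], fit["var_v"], float(rho))
        cls = MarginalizedZipParams if self._kind == "mzip" else ZipParams
        self.params_ = cls(fit.estimates[:q], fit.estimates[q:q + p], re)
        return self._finalize(ds, fit)

    def _per_subject_loglik(self, ds):
        fn = {"zip": loglik_zip, "mzip": loglik_mzip, "hurdle": loglik_hurdle}[self._kind]
        return fn(ds, self._designs(ds), self.params_, self.quad_order,
                  per_subject=True)


class ZIPRandomInterceptModel(_CountEstimator):
    """Zero-inflated Poisson with correlated normal random intercepts."""

    _kind = "zip"


class MarginalizedZIPModel(_CountEstimator):
    """Marginalised ZIP: overall-mean (IDR) parameterisation, robust SEs."""

    _kind = "mzip"

    def __init__(self, binary_terms=None, intensity_terms=None, interactions=None,
                 quad_order=20, rho_fixed=None, robust=True):
        super().__init__(binary_terms, intensity_terms, interactions,
                         quad_order, rho_fixed, robust)

    def idr(self, which, level=0.95):
        return idr_report(self.result_, which, level, robust=self.robust)


class HurdleModel(_CountEstimator):
    """Hurdle (zero-truncated Poisson) model with normal random intercepts."""

    _kind = "hurdle"
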