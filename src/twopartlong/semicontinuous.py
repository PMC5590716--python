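"""Two-part mixed models for longitudinal semicontinuous outcomes.

The outcome Y_ij >= 0 is split into an occurrence indicator Z_ij = 1{Y_ij>0}
modelled by random-intercept logistic regression, and an intensity g(Y_ij)
given Y_ij > 0 modelled by a linear mixed model; the random-intercept pair is
jointly distributed and possibly correlated, which ties the two processes
together.

Two random-effect laws are offered for the binary part:

* ``TwoPartMixedModel`` -- bivariate normal (U_i, V_i): the binary-part
  coefficients have a subject-specific (conditional) interpretation;
* ``BridgeTwoPartModel`` -- a bridge-distributed intercept B_i coupled to a
  normal V_i through the probability integral transform: the binary-part
  coefficients theta are population-averaged (marginal) log odds ratios, and
  the conditional coefficients are theta / phi.

Marginal-mean machinery for the bridge model (conditional-on-positive mean,
overall mean, their analytic bounds, and simulation-based contrasts) lives at
the bottom of the module.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy.special import ndtr
from sklearn.base import BaseEstimator

from .data import DesignMatrices, LongitudinalDataset, TransformSpec, build_designs
from .distributions import BivariateNormalRE, BridgeParams, bridge_inverse_cdf
from .estimation import FitResult, ParamTransform, maximize
from .quadrature import (
    gauss_hermite_rule,
    log_marginal_subjects_1d,
    log_marginal_subjects_2d,
)

__all__ = [
    "TwoPartParams",
    "BridgeTwoPartParams",
    "TwoPartMixedModel",
    "BridgeTwoPartModel",
    "loglik_twopart",
    "loglik_bridge_twopart",
    "fit_twopart",
    "fit_bridge_twopart",
    "conditional_coeffs",
    "conditional_marginal_mean",
    "conditional_mean_bounds",
    "overall_marginal_mean",
    "overall_mean_bounds",
    "marginal_contrast",
]


def _log_sigmoid(x):
    return -np.logaddexp(0.0, -x)


def _segment_starts(codes):
    return np.concatenate([[0], np.flatnonzero(np.diff(codes)) + 1])


@dataclass(frozen=True)
class TwoPartParams:
    """Parameters of the normal-random-intercept two-part mixed model."""

    theta: np.ndarray
    beta: np.ndarray
    re: BivariateNormalRE
    resid_var: float
    transform: TransformSpec = TransformSpec("log")

    def __post_init__(self):
        if self.resid_var <= 0:
            raise ValueError("resid_var must be positive")
        object.__setattr__(self, "theta", np.atleast_1d(np.asarray(self.theta, float)))
        object.__setattr__(self, "beta", np.atleast_1d(np.asarray(self.beta, float)))


@dataclass(frozen=True)
class BridgeTwoPartParams:
    """Parameters of the bridge-marginalised two-part model.

    ``theta_marginal`` are population-averaged binary-part coefficients; the
    conditional (subject-specific) coefficients theta_marginal / phi are
    always derived, never stored.
    """

    theta_marginal: np.ndarray
    beta: np.ndarray
    bridge: BridgeParams
    var_v: float
    rho: float
    resid_var: float
    transform: TransformSpec = TransformSpec("log")

    def __post_init__(self):
        if self.resid_var <= 0 or self.var_v <= 0:
            raise ValueError("variances must be positive")
        if not (-1.0 <= self.rho <= 1.0):
            raise ValueError("rho must lie in [-1, 1]")
        object.__setattr__(
            self, "theta_marginal", np.atleast_1d(np.asarray(self.theta_marginal, float))
        )
        object.__setattr__(self, "beta", np.atleast_1d(np.asarray(self.beta, float)))

    @property
    def theta_conditional(self) -> np.ndarray:
        return self.theta_marginal / self.bridge.phi


# --------------------------------------------------------------------------
# log-likelihoods

def _twopart_pieces(ds: LongitudinalDataset, designs: DesignMatrices, transform):
    y = ds.outcome
    z = (y > 0).astype(float)
    with np.errstate(divide="ignore"):
        gy = np.where(y > 0, transform.forward(np.maximum(y, 1e-300)), 0.0)
    return y, z, gy


def _twopart_cond_loglik(ds, designs, theta_cond, beta, resid_var, transform,
                         bridge_phi=None):
    """Conditional (on random effects) log-likelihood closure for the engine."""
    _, z, gy = _twopart_pieces(ds, designs, transform)
    eta_b = designs.X_binary @ theta_cond
    eta_c = designs.X_intensity @ beta
    codes = ds.subject_codes
    starts = _segment_starts(codes)
    log_norm_const = -0.5 * np.log(2.0 * np.pi * resid_var)

    def cond(u, v):
        U = u[codes]
        V = v[codes]
        if bridge_phi is not None:
            p = np.clip(ndtr(U), 1e-15, 1.0 - 1e-15)
            U = bridge_inverse_cdf(p, bridge_phi)
        lp = eta_b[:, None] + U
        lb = np.where(z[:, None] > 0, _log_sigmoid(lp), _log_sigmoid(-lp))
        resid = gy[:, None] - eta_c[:, None] - V
        lc = z[:, None] * (log_norm_const - resid**2 / (2.0 * resid_var))
        return np.add.reduceat(lb + lc, starts, axis=0)

    return cond


def loglik_twopart(ds, designs, params: TwoPartParams, rule=20, adaptive=True,
                   per_subject=False):
    """Marginal log-likelihood of the normal two-part mixed model.

    The occurrence indicator is derived internally from the outcome; zero
    random-effect variances degrade gracefully to the corresponding
    fixed-effect model (the integral collapses along degenerate directions).
    """
    cond = _twopart_cond_loglik(
        ds, designs, params.theta, params.beta, params.resid_var, params.transform
    )
    ll = log_marginal_subjects_2d(cond, ds.n_subjects, params.re.cov, rule, adaptive)
    return ll if per_subject else float(np.sum(ll))


def loglik_bridge_twopart(ds, designs, params: BridgeTwoPartParams, rule=20,
                          adaptive=True, per_subject=False):
    """Marginal log-likelihood of the bridge-marginalised two-part model.

    The binary-part linear predictor uses the conditional coefficients
    theta / phi plus a bridge intercept built from a standard-normal U_i by
    the probability integral transform, so the integrated binary part is
    logistic in X theta.
    """
    cond = _twopart_cond_loglik(
        ds, designs, params.theta_conditional, params.beta, params.resid_var,
        params.transform, bridge_phi=params.bridge.phi,
    )
    cov = np.array(
        [[1.0, params.rho * np.sqrt(params.var_v)],
         [params.rho * np.sqrt(params.var_v), params.var_v]]
    )
    ll = log_marginal_subjects_2d(cond, ds.n_subjects, cov, rule, adaptive)
    return ll if per_subject else float(np.sum(ll))


# --------------------------------------------------------------------------
# fitting

def _init_binary(Xb, z):
    """Few Newton steps of plain logistic regression for a warm start."""
    th = np.zeros(Xb.shape[1])
    for _ in range(25):
        p = 1.0 / (1.0 + np.exp(-(Xb @ th)))
        W = np.maximum(p * (1 - p), 1e-6)
        g = Xb.T @ (z - p)
        H = (Xb * W[:, None]).T @ Xb + 1e-8 * np.eye(Xb.shape[1])
        step = np.linalg.solve(H, g)
        th = th + step
        if np.max(np.abs(step)) < 1e-8:
            break
    return np.clip(th, -8, 8)


def _init_intensity(Xc, gy, pos):
    Xp, yp = Xc[pos], gy[pos]
    b, *_ = np.linalg.lstsq(Xp, yp, rcond=None)
    resid = yp - Xp @ b
    s2 = float(np.var(resid)) if len(yp) > Xc.shape[1] else 1.0
    return b, max(s2, 1e-3)


def fit_twopart(ds, designs, transform="log", quad_order=20, rho_fixed=None,
                init=None, adaptive=True, robust=False,
                compute_cov=True) -> FitResult:
    """Maximum likelihood fit of the normal two-part mixed model.

    ``rho_fixed`` constrains the random-intercept correlation (0 gives the
    independence model, whose likelihood separates into the two parts; the
    separable structure is exploited for speed).  ``rho_fixed=1`` with free
    variances is the latent-process constraint V_i = alpha U_i.
    """
    if rho_fixed == 0.0 and not robust:
        return _fit_twopart_independent(ds, designs, transform, quad_order,
                                        adaptive, compute_cov)
    tr = TransformSpec(transform)
    y, z, gy = _twopart_pieces(ds, designs, tr)
    q, p = designs.q, designs.p
    names = (
        [f"binary:{n}" for n in designs.binary_names]
        + [f"intensity:{n}" for n in designs.intensity_names]
        + ["var_u", "var_v"]
        + ([] if rho_fixed is not None else ["rho"])
        + ["resid_var"]
    )
    links = ["identity"] * (q + p) + ["log", "log"] + (
        [] if rho_fixed is not None else ["atanh"]
    ) + ["log"]
    pt = ParamTransform(tuple(names), tuple(links))

    if init is None:
        th0 = _init_binary(designs.X_binary, z)
        b0, s2 = _init_intensity(designs.X_intensity, gy, y > 0)
        nat = np.concatenate(
            [th0, b0, [0.5, 0.5], [] if rho_fixed is not None else [0.0], [s2]]
        )
    else:
        nat = np.asarray(init, float)
    if rho_fixed is None:
        idx = names.index("rho")
        nat[idx] = np.clip(nat[idx], -0.99, 0.99)
    x0 = pt.to_unconstrained(nat)

    def unpack(x):
        natv = pt.to_natural(x)
        theta = natv[:q]
        beta = natv[q:q + p]
        var_u, var_v = natv[q + p], natv[q + p + 1]
        rho = rho_fixed if rho_fixed is not None else natv[q + p + 2]
        resid = natv[-1]
        return TwoPartParams(theta, beta, BivariateNormalRE(var_u, var_v, rho),
                             resid, tr)

    def persub(x):
        return loglik_twopart(ds, designs, unpack(x), quad_order, adaptive,
                              per_subject=True)

    def ll(x):
        return float(np.sum(persub(x)))

    fit = maximize(ll, x0, pt, ds.n_subjects, ds.n_obs, quad_order,
                   per_subject_loglik=persub, robust=robust,
                   compute_cov=compute_cov)
    fit.extra["model"] = "twopart"
    fit.extra["transform"] = transform
    fit.extra["binary_names"] = list(designs.binary_names)
    fit.extra["intensity_names"] = list(designs.intensity_names)
    if rho_fixed is not None:
        fit.extra["rho_fixed"] = float(rho_fixed)
    if fit["var_u"] > 10.0 and ds.zero_fraction < 0.05:
        warnings.warn(
            "binary-part variance is large while the zero fraction is small; "
            "the (profile) likelihood surface may be flat and the binary-part "
            "estimates unstable"
        )
    return fit


def _fit_twopart_independent(ds, designs, transform, quad_order, adaptive,
                             compute_cov) -> FitResult:
    """Independence model (rho = 0): the likelihood separates, so the binary
    and intensity parts are maximised on their own 1-D integrals."""
    tr = TransformSpec(transform)
    y, z, gy = _twopart_pieces(ds, designs, tr)
    q, p = designs.q, designs.p
    codes = ds.subject_codes
    starts = _segment_starts(codes)
    eta_fun_b = designs.X_binary
    eta_fun_c = designs.X_intensity
    n = ds.n_subjects

    # ---- binary part: theta, var_u
    pt_b = ParamTransform(
        tuple([f"binary:{m}" for m in designs.binary_names] + ["var_u"]),
        tuple(["identity"] * q + ["log"]),
    )

    def persub_b(x):
        nat = pt_b.to_natural(x)
        theta, su = nat[:q], np.sqrt(nat[q])
        eta = eta_fun_b @ theta

        def cond(a):
            lp = eta[:, None] + su * a[codes]
            lb = np.where(z[:, None] > 0, _log_sigmoid(lp), _log_sigmoid(-lp))
            return np.add.reduceat(lb, starts, axis=0)

        return log_marginal_subjects_1d(cond, n, quad_order, adaptive)

    x0b = pt_b.to_unconstrained(np.concatenate([_init_binary(eta_fun_b, z), [0.5]]))
    fit_b = maximize(lambda x: float(np.sum(persub_b(x))), x0b, pt_b, n, ds.n_obs,
                     quad_order, compute_cov=compute_cov)

    # ---- intensity part: beta, var_v, resid_var
    pt_c = ParamTransform(
        tuple([f"intensity:{m}" for m in designs.intensity_names]
              + ["var_v", "resid_var"]),
        tuple(["identity"] * p + ["log", "log"]),
    )

    def persub_c(x):
        nat = pt_c.to_natural(x)
        beta, sv, s2 = nat[:p], np.sqrt(nat[p]), nat[p + 1]
        eta = eta_fun_c @ beta
        const = -0.5 * np.log(2.0 * np.pi * s2)

        def cond(a):
            resid = gy[:, None] - eta[:, None] - sv * a[codes]
            lc = z[:, None] * (const - resid**2 / (2.0 * s2))
            return np.add.reduceat(lc, starts, axis=0)

        return log_marginal_subjects_1d(cond, n, quad_order, adaptive)

    b0, s2 = _init_intensity(eta_fun_c, gy, y > 0)
    x0c = pt_c.to_unconstrained(np.concatenate([b0, [0.5, s2]]))
    fit_c = maximize(lambda x: float(np.sum(persub_c(x))), x0c, pt_c, n, ds.n_obs,
                     quad_order, compute_cov=compute_cov)

    # ---- assemble in the joint parameter order
    names = (list(pt_b.names[:q]) + list(pt_c.names[:p])
             + ["var_u", "var_v", "resid_var"])
    k = len(names)
    est = np.concatenate([
        fit_b.estimates[:q], fit_c.estimates[:p],
        [fit_b.estimates[q], fit_c.estimates[p], fit_c.estimates[p + 1]],
    ])
    cov = np.full((k, k), np.nan)
    cov_u = np.full((k, k), np.nan)
    xu = np.concatenate([
        fit_b.x_unconstrained[:q], fit_c.x_unconstrained[:p],
        [fit_b.x_unconstrained[q], fit_c.x_unconstrained[p],
         fit_c.x_unconstrained[p + 1]],
    ])
    perm_b = list(range(q)) + [q + p]            # theta.., var_u
    perm_c = list(range(q, q + p)) + [q + p + 1, q + p + 2]
    if compute_cov:
        cov = np.zeros((k, k))
        cov_u = np.zeros((k, k))
        cov[np.ix_(perm_b, perm_b)] = fit_b.cov_model
        cov[np.ix_(perm_c, perm_c)] = fit_c.cov_model
        cov_u[np.ix_(perm_b, perm_b)] = fit_b.cov_unconstrained
        cov_u[np.ix_(perm_c, perm_c)] = fit_c.cov_unconstrained
    pt = ParamTransform(tuple(names),
                        tuple(["identity"] * (q + p) + ["log", "log", "log"]))
    fit = FitResult(
        names=tuple(names), estimates=est,
        loglik=fit_b.loglik + fit_c.loglik,
        cov_model=cov, converged=fit_b.converged and fit_c.converged,
        n_subjects=n, n_obs=ds.n_obs, quad_order=quad_order,
        x_unconstrained=xu, transform=pt, cov_unconstrained=cov_u,
    )
    fit.extra["model"] = "twopart"
    fit.extra["transform"] = transform
    fit.extra["binary_names"] = list(designs.binary_names)
    fit.extra["intensity_names"] = list(designs.intensity_names)
    fit.extra["rho_fixed"] = 0.0
    return fit


def fit_bridge_twopart(ds, designs, transform="log", quad_order=20, rho_fixed=None,
                       init=None, adaptive=True, robust=False) -> FitResult:
    """Maximum likelihood fit of the bridge-marginalised two-part model.

    The reported binary-part coefficients are marginal log odds ratios; use
    :func:`conditional_coeffs` for the subject-specific scale theta / phi.
    """
    tr = TransformSpec(transform)
    y, z, gy = _twopart_pieces(ds, designs, tr)
    q, p = designs.q, designs.p
    names = (
        [f"binary:{n}" for n in designs.binary_names]
        + [f"intensity:{n}" for n in designs.intensity_names]
        + ["phi", "var_v"]
        + ([] if rho_fixed is not None else ["rho"])
        + ["resid_var"]
    )
    links = ["identity"] * (q + p) + ["logit", "log"] + (
        [] if rho_fixed is not None else ["atanh"]
    ) + ["log"]
    pt = ParamTransform(tuple(names), tuple(links))

    if init is None:
        th0 = _init_binary(designs.X_binary, z)
        b0, s2 = _init_intensity(designs.X_intensity, gy, y > 0)
        nat = np.concatenate(
            [th0, b0, [0.5, 0.5], [] if rho_fixed is not None else [0.0], [s2]]
        )
    else:
        nat = np.asarray(init, float)
    if rho_fixed is None:
        idx = names.index("rho")
        nat[idx] = np.clip(nat[idx], -0.99, 0.99)
    x0 = pt.to_unconstrained(nat)

    def unpack(x):
        natv = pt.to_natural(x)
        rho = rho_fixed if rho_fixed is not None else natv[q + p + 2]
        return BridgeTwoPartParams(
            natv[:q], natv[q:q + p], BridgeParams(natv[q + p]),
            natv[q + p + 1], rho, natv[-1], tr,
        )

    def persub(x):
        return loglik_bridge_twopart(ds, designs, unpack(x), quad_order, adaptive,
                                     per_subject=True)

    def ll(x):
        return float(np.sum(persub(x)))

    fit = maximize(ll, x0, pt, ds.n_subjects, ds.n_obs, quad_order,
                   per_subject_loglik=persub, robust=robust)
    fit.extra["model"] = "bridge"
    fit.extra["transform"] = transform
    fit.extra["binary_names"] = list(designs.binary_names)
    fit.extra["intensity_names"] = list(designs.intensity_names)
    cond, cond_se = conditional_coeffs(fit)
    fit.extra["conditional_binary"] = {
        n: {"estimate": float(c), "se": float(s)}
        for n, c, s in zip(designs.binary_names, cond, cond_se)
    }
    fit.extra["var_b"] = float(np.pi**2 * (fit["phi"] ** -2 - 1.0) / 3.0)
    return fit


def conditional_coeffs(fit: FitResult):
    """Subject-specific binary-part coefficients theta/phi of a bridge fit,
    with delta-method standard errors.

    The marginal effects are attenuated by phi; dividing by phi recovers the
    conditional (given random intercept) log odds ratios.
    """
    names = list(fit.names)
    if "phi" not in names:
        raise ValueError("not a bridge-model fit")
    phi = fit["phi"]
    i_phi = names.index("phi")
    idx = [i for i, n in enumerate(names) if n.startswith("binary:")]
    theta = fit.estimates[idx]
    cond = theta / phi
    se = np.empty_like(cond)
    C = fit.cov_model
    for k, i in enumerate(idx):
        g = np.zeros(len(names))
        g[i] = 1.0 / phi
        g[i_phi] = -theta[k] / phi**2
        se[k] = np.sqrt(max(g @ C @ g, 0.0))
    if phi < 0.02 or phi > 0.98:
        warnings.warn("phi estimate is at the boundary; delta-method SEs for "
                      "conditional coefficients are unreliable")
    return cond, se


# --------------------------------------------------------------------------
# marginal means for the bridge model

def _bridge_occ_integrals(x, params: BridgeTwoPartParams, order=80):
    """E[p(U)], E[U p(U)] with p(u) = logit^{-1}(x theta/phi + F_B^{-1}(Phi(u)))."""
    rule = gauss_hermite_rule(order)
    delta = float(np.dot(np.atleast_1d(x), params.theta_conditional))
    pu = np.clip(ndtr(rule.nodes), 1e-15, 1 - 1e-15)
    b = bridge_inverse_cdf(pu, params.bridge.phi)
    p = 1.0 / (1.0 + np.exp(-(delta + b)))
    Ep = float(np.sum(rule.weights * p))
    Eup = float(np.sum(rule.weights * rule.nodes * p))
    return Ep, Eup


def conditional_marginal_mean(x_star, x, params: BridgeTwoPartParams, order=80):
    """Population-averaged mean of g(Y) among positives, E[g(Y) | X*, Y>0].

    Equals X* beta plus a correction E[V | Y>0] that vanishes at rho = 0 and
    otherwise has no closed form; it is evaluated by quadrature.
    """
    xb = float(np.dot(np.atleast_1d(x_star), params.beta))
    if params.rho == 0.0:
        return xb
    Ep, Eup = _bridge_occ_integrals(x, params, order)
    return xb + params.rho * np.sqrt(params.var_v) * Eup / Ep


def conditional_mean_bounds(x_star, x, params: BridgeTwoPartParams):
    """Analytic envelope for the conditional-on-positive marginal mean.

    For rho >= 0 the mean lies in [X* beta, X* beta + sigma_v rho
    (1 + e^{-X theta}) / sqrt(2 pi)]; the inequalities flip for rho <= 0.
    """
    xb = float(np.dot(np.atleast_1d(x_star), params.beta))
    eta = float(np.dot(np.atleast_1d(x), params.theta_marginal))
    term = (np.sqrt(params.var_v) * params.rho * (1.0 + np.exp(-eta))
            / np.sqrt(2.0 * np.pi))
    lo, hi = sorted((xb, xb + term))
    return lo, hi


def overall_marginal_mean(x_star, x, params: BridgeTwoPartParams, order=80):
    """Overall marginal mean E[Y] = E[Y | Y>0] Pr(Y>0).

    Supported transforms: identity (conditional mean is linear) and log
    (lognormal moment of the conditional part).
    """
    tname = params.transform.name
    sv = np.sqrt(params.var_v)
    rule = gauss_hermite_rule(order)
    delta = float(np.dot(np.atleast_1d(x), params.theta_conditional))
    pu = np.clip(ndtr(rule.nodes), 1e-15, 1 - 1e-15)
    b = bridge_inverse_cdf(pu, params.bridge.phi)
    p = 1.0 / (1.0 + np.exp(-(delta + b)))
    xb = float(np.dot(np.atleast_1d(x_star), params.beta))
    if tname == "identity":
        if params.rho == 0.0:
            # exact factorisation: Pr(Y>0) is logistic by the bridge property
            eta = float(np.dot(np.atleast_1d(x), params.theta_marginal))
            return xb / (1.0 + np.exp(-eta))
        # E[p(U) (x*b + rho s_v U)]
        return float(np.sum(rule.weights * p * (xb + params.rho * sv * rule.nodes)))
    if tname == "log":
        # E[Y | U=u, Y>0] is the lognormal mean with location x*b + rho s_v u
        # and variance (1-rho^2) s_v^2 + s_e^2
        s2 = (1.0 - params.rho**2) * params.var_v + params.resid_var
        m = xb + params.rho * sv * rule.nodes + 0.5 * s2
        return float(np.sum(rule.weights * p * np.exp(m)))
    raise ValueError(f"unsupported transform {tname!r} for the overall mean")


def overall_mean_bounds(x_star, x, params: BridgeTwoPartParams):
    """Envelope Pr(Y>0) X* beta <= E[Y] <= Pr(Y>0) X* beta + sigma_v rho /
    sqrt(2 pi) for rho >= 0 (flipped for rho <= 0); identity transform."""
    xb = float(np.dot(np.atleast_1d(x_star), params.beta))
    eta = float(np.dot(np.atleast_1d(x), params.theta_marginal))
    pocc = 1.0 / (1.0 + np.exp(-eta))
    term = np.sqrt(params.var_v) * params.rho / np.sqrt(2.0 * np.pi)
    lo, hi = sorted((pocc * xb, pocc * xb + term))
    return lo, hi


def _params_from_bridge_fit(fit: FitResult, estimates=None) -> BridgeTwoPartParams:
    names = list(fit.names)
    est = fit.estimates if estimates is None else estimates
    q = len(fit.extra["binary_names"])
    p = len(fit.extra["intensity_names"])
    rho = fit.extra.get("rho_fixed")
    if rho is None:
        rho = est[names.index("rho")]
    return BridgeTwoPartParams(
        est[:q], est[q:q + p], BridgeParams(est[names.index("phi")]),
        est[names.index("var_v")], float(rho), est[names.index("resid_var")],
        TransformSpec(fit.extra.get("transform", "log")),
    )


def _setting_to_rows(fit: FitResult, setting: dict):
    """Map a named covariate setting to (x_binary, x_intensity) rows."""
    def row(names):
        out = []
        for n in names:
            if n == "intercept":
                out.append(1.0)
            elif ":" in n:
                a, b = n.split(":")
                out.append(float(setting.get(a, 0.0)) * float(setting.get(b, 0.0)))
            else:
                out.append(float(setting.get(n, 0.0)))
        return np.array(out)

    return row(fit.extra["binary_names"]), row(fit.extra["intensity_names"])


def marginal_contrast(fit: FitResult, setting_a: dict, setting_b: dict,
                      n_draws: int = 2000, seed=None, order: int = 60):
    """Contrast of overall marginal means between two covariate settings.

    Parameters are sampled from the asymptotic normal distribution of the
    estimates (on the unconstrained scale, which keeps phi and variances in
    their domains); the contrast of overall marginal means is computed per
    draw and summarised by its mean and 2.5/97.5 percentiles.
    """
    rng = np.random.default_rng(seed)
    xa_b, xa_c = _setting_to_rows(fit, setting_a)
    xb_b, xb_c = _setting_to_rows(fit, setting_b)

    def contrast(est):
        par = _params_from_bridge_fit(fit, est)
        return (overall_marginal_mean(xa_c, xa_b, par, order)
                - overall_marginal_mean(xb_c, xb_b, par, order))

    point = contrast(fit.estimates)
    cov = fit.cov_unconstrained
    if cov is None or np.allclose(cov, 0.0):
        return {"estimate": point, "ci": (point, point), "n_draws": 0}
    draws_u = rng.multivariate_normal(fit.x_unconstrained, cov, size=int(n_draws),
                                      method="svd")
    vals = np.array([contrast(fit.transform.to_natural(d)) for d in draws_u])
    lo, hi = np.percentile(vals, [2.5, 97.5])
    return {"estimate": float(point), "mean": float(vals.mean()),
            "ci": (float(lo), float(hi)), "n_draws": int(n_draws)}


# --------------------------------------------------------------------------
# sklearn-style estimators

class _PanelEstimator(BaseEstimator):
    """Shared scaffolding: term lists in __init__, panel in fit."""

    def _designs(self, ds: LongitudinalDataset) -> DesignMatrices:
        return build_designs(
            ds,
            binary_terms=self.binary_terms or (),
            intensity_terms=self.intensity_terms or (),
            interactions=self.interactions or (),
        )

    @staticmethod
    def _as_dataset(X) -> LongitudinalDataset:
        if isinstance(X, LongitudinalDataset):
            return X
        return LongitudinalDataset(X)

    def _finalize(self, ds, fit: FitResult):
        self.result_ = fit
        self.names_ = fit.names
        self.coef_ = fit.estimates
        self.loglik_ = fit.loglik
        self.aic_ = fit.aic
        self.converged_ = fit.converged
        self.n_subjects_ = ds.n_subjects
        self.n_obs_ = ds.n_obs
        return self

    def score(self, X, y=None):
        """Mean per-subject log-likelihood at the fitted parameters."""
        ds = self._as_dataset(X)
        return float(np.mean(self._per_subject_loglik(ds)))


class TwoPartMixedModel(_PanelEstimator):
    """Two-part mixed model with correlated normal random intercepts.

    Parameters
    ----------
    binary_terms, intensity_terms : sequences of covariate names for the
        occurrence and intensity design matrices (intercept always first).
    interactions : (a, b) column pairs appended as products to both parts.
    transform : 'log' (default) or 'identity' intensity-scale transform.
    quad_order : Gauss-Hermite order (adaptive recentring per subject).
    rho_fixed : optionally constrain the random-intercept correlation.
    robust : also compute the sandwich covariance.
    """

    def __init__(self, binary_terms=None, intensity_terms=None, interactions=None,
                 transform="log", quad_order=20, rho_fixed=None, adaptive=True,
                 robust=False):
        self.binary_terms = binary_terms
        self.intensity_terms = intensity_terms
        self.interactions = interactions
        self.transform = transform
        self.quad_order = quad_order
        self.rho_fixed = rho_fixed
        self.adaptive = adaptive
        self.robust = robust

    def fit(self, X, y=None):
        ds = self._as_dataset(X)
        designs = self._designs(ds)
        fit = fit_twopart(ds, designs, self.transform, self.quad_order,
                          self.rho_fixed, adaptive=self.adaptive, robust=self.robust)
        self.designs_ = designs
        self.params_ = self._unpack(fit)
        return self._finalize(ds, fit)

    def _unpack(self, fit) -> TwoPartParams:
        q = len(fit.extra["binary_names"])
        p = len(fit.extra["intensity_names"])
        rho = fit.extra.get("rho_fixed")
        if rho is None:
            rho = fit["rho"]
        return TwoPartParams(
            fit.estimates[:q], fit.estimates[q:q + p],
            BivariateNormalRE(fit["var_u"], fit["var_v"], float(rho)),
            fit["resid_var"], TransformSpec(fit.extra["transform"]),
        )

    def _per_subject_loglik(self, ds):
        return loglik_twopart(ds, self._designs(ds), self.params_,
                              self.quad_order, self.adaptive, per_subject=True)


class BridgeTwoPartModel(_PanelEstimator):
    """Bridge-marginalised two-part model: marginal binary-part coefficients.

    Same interface as :class:`TwoPartMixedModel`; after fitting,
    ``conditional_binary_`` holds the subject-specific coefficients
    theta / phi with delta-method SEs, and ``var_b_`` the implied bridge
    random-intercept variance pi^2 (phi^-2 - 1)/3.
    """

    def __init__(self, binary_terms=None, intensity_terms=None, interactions=None,
                 transform="log", quad_order=20, rho_fixed=None, adaptive=True,
                 robust=False):
        self.binary_terms = binary_terms
        self.intensity_terms = intensity_terms
        self.interactions = interactions
        self.transform = transform
        self.quad_order = quad_order
        self.rho_fixed = rho_fixed
        self.adaptive = adaptive
        self.robust = robust

    def fit(self, X, y=None):
        ds = self._as_dataset(X)
        designs = self._designs(ds)
        fit = fit_bridge_twopart(ds, designs, self.transform, self.quad_order,
                                 self.rho_fixed, adaptive=self.adaptive,
                                 robust=self.robust)
        self.designs_ = designs
        self.params_ = _params_from_bridge_fit(fit)
        self.conditional_binary_ = fit.extra["conditional_binary"]
        self.var_b_ = fit.extra["var_b"]
        return self._finalize(ds, fit)

    def _per_subject_loglik(self, ds):
        return loglik_bridge_twopart(ds, self._designs(ds), self.params_,
                                     self.quad_order, self.adaptive,
                                     per_subject=True)

    def overall_mean(self, setting: dict, order: int = 80):
        xb, xc = _setting_to_rows(self.result_, setting)
        return overall_marginal_mean(xc, xb, self.params_, order)

    def contrast(self, setting_a: dict, setting_b: dict, n_draws=2000, seed=None):
        return marginal_contrast(self.result_, setting_a, setting_b, n_draws, seed)
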