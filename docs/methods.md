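# Methods

`twopartlong` estimates regression models for longitudinal outcomes with
excess zeros by maximum likelihood. This note records the models, the
numerical choices behind the likelihoods, what the simulators emulate, and
the limits of what the test suite demonstrates.

## Models

### Two-part mixed model for semicontinuous outcomes

A nonnegative outcome `Y_ij` (subject `i`, visit `j`) is decomposed into an
occurrence indicator `Z_ij = 1{Y_ij > 0}` and an intensity `g(Y_ij)` given
`Y_ij > 0`, where `g` is `log` (default) or the identity:

    logit Pr(Z_ij = 1 | U_i) = X_ij θ + U_i
    g(Y_ij) | Y_ij > 0       = X*_ij β + V_i + ε_ij,   ε_ij ~ N(0, σ_e²)

with `(U_i, V_i)` bivariate normal, variances `σ_u², σ_v²` and correlation
`ρ`. The correlation couples the two processes: with `ρ > 0`, subjects who
are more likely to have any outcome also tend to have larger outcomes. The
likelihood is the product over subjects of a two-dimensional integral of the
Bernoulli × Gaussian conditional likelihood against the random-effect
density. The occurrence indicator is always derived from the outcome, never
supplied, which removes a class of inconsistent inputs.

The intensity likelihood is written on the transformed scale (the density of
`g(Y)`); no Jacobian term is added for the log transform, so log-likelihoods
are comparable across fits of the same data and transform, which is the use
AIC is put to here.

The constraint `ρ = 0` makes the likelihood separate into the two parts; the
independence fit exploits this and maximises two small problems instead of
one joint one. The latent-process constraint (a single underlying random
effect, `V_i = α U_i`) is available as the constrained refit `rho_fixed=1`,
not as a separate model class.

### Bridge-marginalised two-part model

Replacing the normal `U_i` with a bridge-distributed `B_i` (parameter
`φ ∈ (0,1)`, variance `π²(φ⁻² − 1)/3`) makes the *integrated* binary part
logistic again: marginal coefficients `θ` and conditional coefficients
`θ/φ` coexist in one model, and a fitted model reports both (delta-method
standard errors for the ratio). The correlated pair `(B_i, V_i)` is built
from a standard bivariate normal by the probability integral transform
`B = F_B⁻¹(Φ(U))`; the transformation preserves the correlation only
approximately, which is the documented behaviour of this construction (the
test suite checks ±0.05 at ρ = 0.9).

Marginal-mean machinery for this model:

* conditional-on-positive mean `E[g(Y) | X*, Y>0] = X*β + E[V | Y>0]`, the
  correction evaluated by quadrature (it vanishes at ρ = 0) and bounded by
  `σ_v ρ (1 + e^{−Xθ}) / √(2π)`;
* overall mean `E[Y] = E[Y | Y>0] Pr(Y>0)` for the identity and log
  transforms (the log case uses the lognormal moment of the conditional
  part), bounded by `Pr(Y>0) X*β + σ_v ρ / √(2π)`;
* covariate contrasts of overall means with percentile intervals obtained by
  sampling parameters from the asymptotic normal distribution of the
  estimates. Sampling happens on the unconstrained scale (log variances,
  logit φ, atanh ρ) so every draw is a valid parameter point.

The bound terms were derived from `E[U⁺] = 1/√(2π)` for a standard normal
`U` and are validated in the tests against Monte-Carlo oracles rather than
taken on faith.

### Zero-inflated Poisson models with random intercepts

A partially latent `Z_ij` mixes a structural zero with
`Poisson(μ^C_ij)`, `log μ^C_ij = X*_ij β + log O_ij + V_i`, with
`(U_i, V_i)` correlated normal. `Z` is latent at zero observations, so the
zero contribution is `(1−p) + p e^{−μ}` inside the integral. The hurdle
variant gives all zeros to the Bernoulli part and uses a zero-truncated
Poisson for positives; it is provided with normal intercepts only.

The **marginalised ZIP** reparameterises to the subject-specific overall
mean `ν^C_ij = E[Y_ij | X, W_i]`, `log ν^C_ij = X*_ij α + log O_ij + W_i`,
so each `α_k` is directly a subject-specific log incidence density ratio.
The latent-class mean is recovered through the matching term

    δ_ij = log O_ij + log{1 + exp(−X_ij θ − U_i)} + X*_ij α + W_i,

never stored. Robust (sandwich) standard errors are the default report for
this family: subjects are the independent units, per-subject scores are
computed by central finite differences of the per-subject log-likelihood
vector, and the covariance is `A⁻¹ B A⁻ᵀ` with `A` the observed information.
Offsets enter the count/overall-mean predictor only; a flag can add them to
the zero-inflation logit but defaults to off.

### Mover-stayer count models

Count increments are Poisson with mean `u_i Λ_ij`,
`Λ_ij = O_ij λ₀ exp(X_ij β)`, and the frailty `U_i` has a two-part law:
point mass `π` at zero (stayers, who can never have an event) plus a
positive density for movers. Three frailty families:

* unit-mean gamma (shape = rate = 1/θ): can pile mass near zero when θ > 1,
  so it absorbs slow-transitioning movers instead of calling them stayers;
* unit-mean inverse Gaussian (shape ψ): density vanishes at zero;
* compound Poisson `U = Σ_{j≤K} L_j`, `K ~ Poisson(rate)`,
  `L_j ~ Exp(ν)`: its atom ties the stayer probability to `exp(−rate)`, and
  identifiability requires `λ₀ ≡ 1` (the frailty mean `rate/ν` carries the
  scale). The density on `u > 0` is
  `exp(−rate − νu) √(ν·rate/u) I₁(2√(ν·rate·u))`; this prefactor reading was
  verified against the series expansion of the Poisson-sum construction and
  a simulation oracle.

The unit-mean constraint for gamma/IG is baked into the parameter types —
it is the identifiability convention, not an option. The ever-event
indicator `c*_i = 1{Σ_j y_ij > 0}` is always computed from the data; the
stayer atom enters only all-zero subjects' likelihood terms. An
observation-level unit-mean gamma effect (dispersion `θ^nb`) turns the
Poisson kernel into a negative binomial; `θ^nb = 0` recovers the Poisson
class, and the gamma-frailty NB model with patient-level dispersion → 0 is
the ZINB with patient-level zero inflation.

Inference helpers: profile likelihood for `π` (grid default 41 points on
[0, 0.95], inner parameters re-maximised with warm starts), the boundary
likelihood-ratio test with the 50:50 point-mass/χ²₁ null (95% critical value
2.706), empirical-Bayes posterior frailty means and mover probabilities, and
a Pearson table of observed vs expected count increments. The expected
probabilities `e_ij(y)` mix the stayer atom with the mover predictive
distribution integrated over the *full* posterior of `u_i` given all of the
subject's data (plugging in only the posterior mean is the cruder
alternative; full mixing uses the same quadrature grid at no extra cost).
The display table uses categories (0 without / 0 with previous events, 1-4,
>4); the statistic expands >4 into 4..8 and >8, merging any zero-expectation
category with its neighbour.

## Numerics

* **Gauss-Hermite quadrature.** Probabilists' nodes with weights normalised
  against N(0,1); default order 20. The engine evaluates all subjects at
  once and, by default, recentres the rule at each subject's posterior mode
  with curvature-based rescaling ("adaptive" quadrature). The mode search is
  a vectorised damped Newton iteration with finite-difference derivatives;
  if the curvature is not usable the subject falls back to the unshifted
  rule. Correlated pairs are handled by Cholesky rotation; a singular
  covariance (|ρ| = 1 or a zero variance) collapses to a one-dimensional
  integral along the non-degenerate direction, which is what makes the
  latent-process refit and no-random-effect reductions work without special
  cases.
* **Positive frailty integrals.** On the log-frailty axis, composite
  Gauss-Legendre panels over an adaptively widened window: the window grows
  until the integrand has dropped 35 log units below its per-subject mode on
  both sides (small-shape gamma posteriors have power-law tails that a fixed
  ±k·sd window truncates), then is split into panels of at most ~6 posterior
  sds. The gamma family without observation-level dispersion uses the exact
  negative-binomial closed form instead; the quadrature path agrees with it
  to ~1e-9, which the tests pin down.
* **All mixing in the log domain.** Densities are exposed in log form and
  likelihood code consumes only those; `logsumexp` everywhere; the Bessel
  factor of the compound-Poisson density uses the exponentially scaled
  `ive` so large arguments cannot overflow.
* **Optimisation.** Quasi-Newton (BFGS) on an unconstrained scale: log for
  variances and positive parameters, atanh for correlations, logit for
  probabilities and φ. A couple of damped central-difference Newton steps
  polish the BFGS solution (finite-difference BFGS stalls around 1e-6).
  Standard errors come from a central-difference Hessian on the
  unconstrained scale, mapped back by the delta method; Wald intervals are
  computed on the unconstrained scale and mapped back so they respect
  parameter domains. Warm starts: plain logistic regression for binary
  parts, least squares on positives for intensity parts, variance
  components at 0.5, ρ at 0.
* **Degenerate and boundary cases.** A stayer probability estimated at the
  boundary is flagged and the profile likelihood recommended (the
  logit-scale optimiser cannot represent π = 0 exactly); `rho_fixed`
  constraints bypass the atanh parameter entirely; identity-transform
  simulation clips non-positive intensity draws to a tiny positive value and
  records the count (the normal intensity model is an idealisation there).

## Simulators

One generator per family draws exactly from the generative story and
returns a truth side channel (random effects, latent indicators) that tests
may condition on; fits never see it. Three presets emulate the structure of
the motivating data situations:

* `haq_like` — bridge two-part model, identity transform, ~30.6% zeros
  across ~2,000 subject-visits (marginal occurrence intercept 0.77 with a
  sex covariate, φ = 0.4861, σ_v² = 0.29, σ_e² = 0.09, ρ = 0.9, ~5.5 visits
  per subject);
* `uavi_like` — marginalised ZIP, two randomised arms, 4 visits, ~84%
  zeros (occurrence intercept −0.8, overall-mean intercept −0.3, treatment
  log-IDR −0.8, var_u = 4, var_v = 1.5, ρ = −0.6);
* `damage_like` — gamma-frailty mover-stayer, π = 0.3, slow baseline rate
  0.25/year, 4-7 irregularly spaced visits with exposure offsets equal to
  inter-visit gaps.

Where the emulated study reports a rate (30.6% zeros, 84% zeros), the preset
parameters were calibrated once to reproduce it; other values are round
numbers in the range the corresponding analyses report. The presets emulate
*structure* — zero inflation, visit schedules, offsets, arm assignment —
not the full covariate joint distribution, measurement error, or informative
dropout of real cohorts; passing tests say the estimators recover the
generative models at these designs, not that any real dataset satisfies
those models.

## The misspecification-bias study

With correlated random intercepts, fitting the two parts independently
(ρ ≡ 0) biases the continuous part: subjects with large `U` contribute more
(and larger) positive observations, and since `E[V] = 0` overall, the
selected `V`s are positive on average. The study design is two visits
(t = 0, 1) and an equally likely binary group, with `θ₁ = −1`,
`θ₂ = log 2`, `σ_e² = 0.08` and defaults `σ_u² = 4`, intraclass correlation
`ψ = σ_v²/(σ_v²+σ_e²) = 0.7` (this `ψ` is unrelated to the
inverse-Gaussian shape; they live in different modules).

`asymptotic_bias` holds the variance components at truth and solves the
expected independence-model score equations for β under the true correlated
law. Those equations are linear in β, so the damped-Newton root-find
converges in a single step: the probability limit is
`β* = β + M⁻¹ b`, where `M` and `b` average the per-occurrence-pattern GLS
cross-products and the `E[V | pattern]` selection terms over the four
(t, group) cells and the occurrence patterns, with the pattern
probabilities and `E[V | pattern] = ρ σ_v/σ_u · E[U · 1(pattern)]`
integrated over `U` by quadrature. The bias is therefore free of the true
β, which the tests confirm numerically over random β vectors rather than
assume. `finite_sample_bias` runs the parallel simulation experiment
(draw from the correlated truth, refit with ρ ≡ 0 via the fast separable
path) and must bracket the asymptotic value within Monte-Carlo error.

## Problem sizes used by the test suite

Fits in the recovery and calibration experiments use quadrature order 10-20
and panels of 200-400 subjects with 10-60 replicates per experiment, and the
finite-sample bias check uses 30 replicates of 2,000 subjects; these sizes
put the asymptotic approximations well inside their working range while
keeping the whole suite runnable on a single CPU in a coffee break. The
pooled-coverage checks use the package's 2-sigma Wald intervals (computed on
the unconstrained scale), which are the better-calibrated object at these
sample sizes.

## Known limitations

* Random slopes are deliberately out of scope; all models are
  random-intercept only.
* The bridge-hurdle combination, marginalised ZINB, GEE and Bayesian
  estimation paths are not provided.
* The stayer probability is a single constant π; covariate-dependent π is
  an easy extension but excluded here.
* Wald intervals for variance-type parameters are reported on the
  transformed scale mapped back; profile intervals are available only
  for π.
* The Poisson approximation for bounded count processes (e.g. a finite
  number of joints) is inherited from the modelling tradition, not fixed
  here.
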