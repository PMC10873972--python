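# Methods

## Model

For a failure time `T`, censoring time `C`, observed time `Y = min(T, C)`
and event indicator `δ = I(T ≤ C)`, the package models the τ-th quantile of
the *residual life* `T − t` of subjects still event-free at `t`:

    log Q_{T−t}(τ | T ≥ t, W, Z(t)) = α(τ, t)ᵀ W + β(τ, t)ᵀ Z(t),

where `W = (1, W₁, …, W_p)` are time-fixed covariates (intercept implicit in
the code: `W` stores the p non-constant covariates and the leading 1 is
added at design time) and `Z(t)` holds q longitudinal biomarkers observed on
a shared planned visit schedule `t₁ < … < t_D`, subject to per-visit
attendance indicators `η_j`.  Irregular per-subject visit times are not
supported; the attendance indicator is the missingness mechanism.

Each coefficient function is expanded in L+1 predefined basis functions,
`α_j(t) = Σ_l a_{j,l} f_l(t)`, giving a finite parameter γ of length
`d = (p+1+q)(L+1)` with block layout `(a₀, …, a_p, b₁, …, b_q)`.  The
default basis is the fractional polynomial set `{1, log t, √t, 1/√t}`
(presets add `1/t`, the alternative set `{1, 1/√t, t, t²}`, and cubic
B-splines with 0–2 interior knots).  All fractional default terms require
`t > 0`; evaluation at 0 is a domain error rather than a clamped value.

## Estimation

Censoring is handled by inverse-probability-of-censoring weighting: the
censoring survival function `G(t) = P(C > t)` is estimated by the
product-limit method with censoring as the event.  Tie convention: failures
precede censorings at a shared time, so the censoring risk set at its own
jump excludes same-time failures; `Ĝ` is evaluated right-continuously,
including at `Y_i`.  A failure beyond the largest censoring time would give
`Ĝ(Y) = 0` and an infinite weight; such terms are dropped with a warning
(under the built-in designs censoring support is bounded at 4, so this has
essentially zero probability, but the guard is mandatory).

The nonsmooth estimating function sums, over subject-visits with `η_ij = 1`
and `Y_i > t_j`, the terms
`U_ij { I(log(Y_i − t_j) ≤ γᵀU_ij) δ_i Ĝ(t_j)/Ĝ(Y_i) − τ } / n` with
`U_ij` the Kronecker design row.  Its root is obtained exactly as the
minimizer of a weighted-L1 objective with two pseudo-observations at a huge
response `M = 10⁶`: one pseudo-row `−Σ U_ij w_ij / n` and one
`2τ Σ U_ij η_ij I(Y_i > t_j) / n`.  With these rows the objective's
subgradient equals exactly twice the estimating function, so the L1
minimizer is the estimating-equation root; the minimization is an exact
linear program (residual splitting, solved with HiGHS via
`scipy.optimize.linprog`).  The coefficient `2τ` on the second pseudo-row is
what makes this identity hold and is enforced by a test comparing the LP
solution's estimating-function value against the largest active-term bound,
not assumed.  Terms with `Y_i − t_j` positive but tiny keep their exact log
value; no flooring is applied.

The induced-smoothed estimator replaces the indicator by
`Φ((γᵀU_ij − log(Y_i − t_j)) / √(U_ijᵀ H U_ij))` with a symmetric
positive-definite smoothing matrix `H` of norm O(1/n); the default is
`H = I_d / n` with `d = dim(γ)` (a scalar multiplier is configurable).  The
smoothed equation is solved by damped Newton iteration on the analytic
Jacobian, initialized at the nonsmooth LP estimate, with up to 20
step-halvings per iteration; convergence requires the sup-norm of the
estimating function to fall below 1e−8.  If the Jacobian's condition number
exceeds 1e12 the solver falls back to a derivative-free root polish
(Powell hybrid).  Non-convergence is reported in the `FitResult`, never
silently ignored.  Estimation is deterministic given the data; all
stochastic components (resampling, simulation) take explicit seeds.

## Variance

The covariance of the smoothed estimate is the sandwich
`Σ = (Ã⁻¹)ᵀ V̂ (Ã⁻¹)`.  The slope matrix is the analytic derivative of the
smoothed estimating function,

    Ã = (1/n) Σ_ij η_ij I(Y_i > t_j) δ_i Ĝ(t_j)/Ĝ(Y_i)
        φ(z_ij) U_ij U_ijᵀ / √(U_ijᵀ H U_ij),

with φ the standard-normal *density* (the chain rule through Φ produces φ;
a CDF here would not be a Jacobian), verified against central finite
differences to 1e−5 relative error.  `V̂` is the sample covariance of K
(default 200) multiplier-perturbed estimating functions: each replicate
draws i.i.d. exponential(1) subject weights θ_i, multiplies subject i's
entire contribution by θ_i, and *refits the censoring Kaplan–Meier with the
same weights* (both event counts and risk sets θ-weighted).  γ is never
re-estimated, which is the source of the method's speed relative to a full
bootstrap of the nonsmooth estimator (kept in the package as a slow
reference path).  Both the estimating function and its perturbed version
carry the 1/n prefactor, and `Σ` is reported directly as the covariance of
γ̂ with no extra n factors; this scaling convention is validated empirically
by the ESE/ASE calibration test rather than asserted.  Pointwise standard
errors of coefficient functions use the delta method on the (L+1)-sized
diagonal blocks of Σ, with Wald 95% limits at ±1.96 SE.

## Prediction and accuracy measures

The predicted τ-quantile residual life at `t` is
`Q^p = exp(α̂(τ,t)ᵀ[1, W] + β̂(τ,t)ᵀZ(t))`.  Two measures are implemented:

* `MAE_p = mean |min(T − t, L − t) − Q^p|` over subjects with `T > t`; only
  the true residual is truncated at `L − t` (the printed formula truncates
  the truth, not the prediction, and we follow it literally).  Requires the
  true failure time, hence computed on simulated test sets.
* The truncated IPCW C-index: among pairs with `δ_i = 1`,
  `0 < Y_i − t < Y_j − t` and `Y_i < L`, the proportion with concordantly
  ordered predictions, weighted by `δ_i {Ĝ(Y_i)/Ĝ(t)}⁻²`, where `Ĝ` is the
  evaluation set's own censoring estimate.  Prediction ties count as
  discordant (strict inequality).  The index is invariant to strictly
  increasing transforms of the predictions.

The truncation constant defaults to the upper 5% point (95th percentile) of
the test set's censoring times — i.e. close to but below the maximum
censoring time, which is the operative requirement; it is configurable.

## Synthetic-data designs

Three generative designs validate the estimators; their parameters are the
study conditions, not tuning knobs.

* **Setup I** (correctly specified, constant coefficients): W ~ Bern(0.5);
  T exponential with rate 1.5 (W = 0) or 1.0 (W = 1) — memorylessness makes
  the model exact with α₀ = log(−log(1−τ)/1.5), α₁ = log 1.5 ≈ 0.41,
  β = 0; the noise biomarker is Unif(−1, 1) per visit.  Attendance
  probabilities (0.75, 0.9) by W.  Analytic censoring fraction ≈ 18.6%.
* **Setup II** (correctly specified, time-varying coefficients):
  λ ~ Unif(0.5, 1.5); T Weibull shape 2 with survival `exp(−λt²)` (drawn by
  inversion `T = √(−log U / λ)`, the parameterization forced by the
  residual-quantile closed form `√(−log(1−τ)/λ + t²) − t`); the biomarker
  is the deterministic λ-transform making the model hold with
  α₀(t) = log t, α₁ = 0, β(t) = √t.  Attendance (0.5, 0.7).  Censoring
  ≈ 21%.
* **Setup III** (misspecified): Setup II's cohort with the biomarker
  rescaled so the true β(t) = 0.1(t+1)² + 0.1/t, which lies outside the
  span of the default basis.  Setups II and III consume identical random
  streams for (W, T, C, attendance) at the same seed, so comparisons are
  paired.

All setups share the censoring mixture `C = κ·Unif(0,4) + 4(1−κ)` with
κ ~ Bern(0.9) (mean 2.2) and a 12-visit schedule on [0.1, 1]; attendance is
`η_ij = I(Y_i ≥ t_j) ζ_ij` with ζ Bernoulli by W.  The generators emulate
scheduled-visit cohort data with missed visits and bounded administrative
censoring; they do not emulate irregular visit timing, measurement error in
the biomarker, covariate-dependent censoring, or informative missingness —
passing tests therefore say nothing about those features of real cohorts.

## Problem sizes used in the validation suite

The replication studies run at n = 400 with 200 replications (the reference
design uses 1000), resampling size K = 200, evaluation times
{0.1, 0.2, 0.5, 0.8}; the prediction study uses 100 replications with
training n = 400 and test n = 2,000; CI coverage is assessed over 100
replications pooled across coefficients and times.  These sizes are the
package's own choice of validation scale; biases are judged against
Monte-Carlo standard errors computed from the same replications.

## Numerical choices and limitations

* LP degeneracy: a rank-deficient stacked design raises an error naming the
  collinear coefficient blocks before the solver runs.
* The smoothed/nonsmooth agreement check compares coefficient functions at
  the evaluation times against the estimate's own delta-method SEs; near
  t = 0.1 the fractional basis extrapolates aggressively and both
  estimators are intrinsically noisy there (visible in the reference
  standard errors as well).
* Quantile levels are estimated separately; nothing enforces monotonicity
  of `Q^p` across τ (quantile crossing), and no joint-τ estimation is
  provided.
* Only marginal (covariate-independent) censoring is supported; a
  regression model for the censoring distribution is out of scope.
* Estimation near very high censoring or at τ beyond the identifiable range
  surfaces as non-convergence or LP degeneracy rather than being masked.
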