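# qreslife

Quantile residual-life regression for right-censored survival data with
scheduled longitudinal covariates, using induced-smoothed IPCW estimating
equations and a multiplier-resampling sandwich variance.

## What problem this solves

In long-running cohorts (the motivating setting is biomarker follow-up of
chronic-disease patients, e.g. CD4 cell counts in HIV care), the clinically
useful question at a follow-up visit is *how much longer* until the event,
given survival so far and the biomarker value measured today.  Survival
times are right-skewed and right-censored, so `qreslife` models quantiles
of the residual life `T − t` directly:

    log Q_{T−t}(τ | T ≥ t, W, Z(t)) = α(τ, t)ᵀ W + β(τ, t)ᵀ Z(t)

with time-fixed covariates `W`, longitudinal covariates `Z(t)` observed on
a planned visit schedule with missed visits, and time-varying coefficient
functions expanded in a basis (default fractional polynomials
`{1, log t, √t, 1/√t}`; B-splines available).  No parametric distribution
is assumed for `T`.

Two estimators of the stacked basis coefficients γ are provided:

* **nonsmooth** — the IPCW estimating equation solved exactly as a weighted
  L1 linear program with large-M pseudo-observations (HiGHS);
* **induced smoothed** (recommended) — the indicator inside the estimating
  function is replaced by a normal CDF with bandwidth matrix `H = I/n`,
  giving a differentiable equation solved by damped Newton iteration; it
  shares the nonsmooth estimator's limit law, and its smoothness admits a
  *sandwich* covariance `(Ã⁻¹)ᵀ V̂ (Ã⁻¹)` whose middle matrix is estimated
  by exponential-multiplier resampling of the estimating function (with the
  censoring Kaplan–Meier refit per replicate) — no re-estimation of γ,
  which makes variance estimation substantially cheaper than bootstrapping
  the nonsmooth estimator.

Dynamic prediction (`Q^p = exp(γ̂ᵀU(t))`) comes with two accuracy measures:
truncated mean absolute error `MAE_p` (calibration) and a truncated IPCW
C-index (discrimination).  Three synthetic-data designs with known
closed-form coefficient functions are built in for validation; see
`docs/methods.md` for the model, conventions, and design details.

## Worked example

Fit the induced-smoothed estimator at the median on a simulated cohort
(Weibull failures, subject-specific rate, informative biomarker; n = 400,
~21% censored):

```python
import qreslife as q

sim = q.simulate_setup2(400, tau=0.5, seed=7)     # truth: alpha0=log t, beta=sqrt t
fit = q.induced_smoothing_estimate(sim.data, 0.5, q.fractional_polynomial_basis())
comp = q.estimate_variance(fit, K=200, seed=1)    # resampling sandwich
print(q.results_table(fit, [0.2, 0.5, 0.8], comp.Sigma).round(3))
```

```
 tau   t coefficient     PE    SE  ci_lower  ci_upper
 0.5 0.2      alpha0 -1.358 0.339    -2.022    -0.694
 0.5 0.5      alpha0 -0.638 0.106    -0.845    -0.431
 0.5 0.8      alpha0 -0.278 0.272    -0.811     0.255
 0.5 0.2      alpha1 -0.066 0.094    -0.251     0.118
 0.5 0.5      alpha1 -0.034 0.144    -0.316     0.247
 0.5 0.8      alpha1 -0.084 0.240    -0.553     0.386
 0.5 0.2       beta1  0.364 0.118     0.134     0.595
 0.5 0.5       beta1  0.705 0.204     0.305     1.104
 0.5 0.8       beta1  0.856 0.342     0.186     1.526
```

Read: the estimated intercept function tracks `log t` (−1.36 vs −1.61 at
t = 0.2, −0.64 vs −0.69 at t = 0.5), the non-informative fixed covariate's
coefficient is near 0, and the biomarker effect tracks `√t` (0.70 vs 0.71
at t = 0.5); Wald 95% intervals cover the truths.  Predicted median
residual life for one subject at t = 0.5:

```python
t = 0.5
q.predict_residual_life(fit, W=[0.0], Z_at_t=[0.114], t=t)   # -> 0.573
```

against the closed-form truth 0.542 for that subject's rate — i.e. the
model predicts about 0.57 time units of remaining life at the median.

The same workflows are available from a shell:

```sh
qreslife simulate --setup II --n 400 --tau 0.5 --seed 7 --out out/sim
qreslife fit --data out/sim/data.csv --tau 0.5 --times 0.2,0.5,0.8 --out out/fit
qreslife predict --fit out/fit/fit_tau0.5.json --newdata profiles.csv --out out/pred
```

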