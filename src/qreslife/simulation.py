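"""Synthetic-data generators and simulation-study drivers.

Three generative designs exercise the model:

* **Setup I** — single binary fixed covariate, non-informative time-varying
  covariate.  W ~ Bernoulli(0.5); failure times are exponential with rate
  1.5 when W = 0 and rate 1.0 when W = 1 (by memorylessness the residual
  quantile model then holds exactly with constant coefficients
  alpha_0 = log(-log(1-tau)/1.5), alpha_1 = log 1.5, beta = 0).
* **Setup II** — informative time-varying covariate.  Failure times are
  Weibull with shape 2 and subject-specific rate lambda_i ~ Unif(0.5, 1.5)
  (survival exp(-lambda t^2)); Z_i(t) is the deterministic transform of
  lambda_i that makes the model hold with alpha_0(t) = log t, alpha_1 = 0
  and beta(t) = sqrt(t).
* **Setup III** — as Setup II but Z is rescaled so the true beta(t) =
  0.1 (t+1)^2 + 0.1/t, which lies outside the span of the default
  fractional-polynomial basis: a misspecification stress test.

All setups share the censoring mixture C = kappa Unif(0, 4) + 4 (1 - kappa)
with kappa ~ Bernoulli(0.9) (mean censoring time 2.2), a planned schedule of
12 visits on [0.1, 1], and visit attendance eta_ij = I(Y_i >= t_j) zeta_ij
with zeta_ij ~ Bernoulli(p_V0 or p_V1 according to W).  Attendance
probabilities default to (0.75, 0.9) in Setup I and (0.5, 0.7) in
Setups II/III.  Setups II and III consume identical random streams for
(W, T, C, attendance) at the same seed, so misspecification comparisons are
paired.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd

from .basis import BasisSet, fractional_polynomial_basis
from .censoring import fit_censoring_km
from .data import StudyData
from .estimators import (
    EstimatorControl,
    SmoothingConfig,
    induced_smoothing_estimate,
    nonsmooth_estimate,
)
from .prediction import c_index, mae_p, predict_many
from .variance import coefficient_function_se, estimate_variance

__all__ = [
    "VISIT_SCHEDULE",
    "SimulationConfig",
    "TruthFunctions",
    "SimulationResult",
    "simulate_setup1",
    "simulate_setup2",
    "simulate_setup3",
    "true_coefficients",
    "run_simulation_study",
    "run_prediction_study",
]

#: shared planned visit schedule (12 visits)
VISIT_SCHEDULE = np.array([0.1, 0.15, 0.2, 0.25, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9, 1.0])

#: exponential failure rates for W = 0 and W = 1 in Setup I
_SETUP1_RATES = (1.5, 1.0)

_DEFAULT_EVAL_TIMES = (0.1, 0.2, 0.5, 0.8)


@dataclass
class SimulationConfig:
    """Configuration for a replication study."""

    setup: str = "I"                  # "I", "II" or "III"
    n: int = 400
    tau: float = 0.5
    replications: int = 200
    seed: int = 0
    evaluation_times: tuple = _DEFAULT_EVAL_TIMES
    estimator: str = "induced_smooth"  # or "nonsmooth"
    K: int = 200                       # resampling size; 0 disables SEs
    visit_probabilities: tuple | None = None
    basis: BasisSet | None = None
    n_test: int = 10000                # prediction study only
    smoothing_scale: float = 1.0

    def __post_init__(self):
        if self.setup not in ("I", "II", "III"):
            raise ValueError(f"unknown setup {self.setup!r}")
        if not 0 < self.tau < 1:
            raise ValueError("tau must lie in (0, 1)")
        if self.n < 2:
            raise ValueError("n must be at least 2")
        if self.visit_probabilities is not None:
            pv = self.visit_probabilities
            if not all(0 < x <= 1 for x in pv):
                raise ValueError("visit probabilities must lie in (0, 1]")


@dataclass
class TruthFunctions:
    """Closed-form true coefficient functions for one setup and tau."""

    setup: str
    tau: float

    def coefficients(self, t):
        return true_coefficients(self.setup, self.tau, t)

    def alpha0(self, t):
        return self.coefficients(t)[0]

    def alpha1(self, t):
        return self.coefficients(t)[1]

    def beta(self, t):
        return self.coefficients(t)[2]

    def residual_quantile(self, t, W, Z_at_t):
        a0, a1, b = self.coefficients(t)
        return np.exp(a0 + a1 * np.asarray(W) + b * np.asarray(Z_at_t))


def true_coefficients(setup: str, tau: float, t):
    """Exact (alpha_0, alpha_1, beta) at time(s) t."""
    t = np.asarray(t, dtype=float)
    if np.any(t <= 0):
        raise ValueError("evaluation times must be positive")
    ones = np.ones_like(t)
    if setup == "I":
        rate0 = _SETUP1_RATES[0]
        a0 = np.log(-np.log1p(-tau) / rate0) * ones
        a1 = np.log(_SETUP1_RATES[0] / _SETUP1_RATES[1]) * ones
        b = 0.0 * ones
    elif setup == "II":
        a0, a1, b = np.log(t), 0.0 * ones, np.sqrt(t)
    elif setup == "III":
        a0, a1, b = np.log(t), 0.0 * ones, 0.1 * (t + 1.0) ** 2 + 0.1 / t
    else:
        raise ValueError(f"unknown setup {setup!r}")
    if t.ndim == 0:
        return float(a0), float(a1), float(b)
    return a0, a1, b


@dataclass
class SimulationResult:
    """Generated cohort with its latent variables and truth functions.

    ``data`` (the validated :class:`StudyData`) is assembled lazily so that
    large calibration draws that only need the latent arrays stay cheap.
    """

    setup: str
    tau: float
    truth: TruthFunctions
    T: np.ndarray
    C: np.ndarray
    W: np.ndarray                       # (n,) binary fixed covariate
    eta: np.ndarray                     # (n, D)
    Z: np.ndarray                       # (n, D) observed biomarker values
    lam: np.ndarray | None = None       # Setup II/III Weibull rates
    visit_schedule: np.ndarray = field(default_factory=lambda: VISIT_SCHEDULE.copy())
    _data: StudyData | None = field(default=None, repr=False)

    @property
    def Y(self) -> np.ndarray:
        return np.minimum(self.T, self.C)

    @property
    def delta(self) -> np.ndarray:
        return (self.T <= self.C).astype(int)

    @property
    def data(self) -> StudyData:
        if self._data is None:
            Z = np.where(self.eta[:, :, None] == 1, self.Z[:, :, None], np.nan)
            self._data = StudyData.from_arrays(
                self.Y, self.delta, self.W[:, None], self.eta, Z,
                self.visit_schedule,
            )
        return self._data

    def z_at(self, t: float) -> np.ndarray:
        """True biomarker value at an arbitrary time t (Setups II/III)."""
        if self.lam is None:
            raise ValueError("Setup I has no deterministic biomarker path")
        return _z_path(self.setup, self.tau, self.lam, float(t))

    def censoring_proportion(self) -> float:
        return float(np.mean(self.delta == 0))


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def _censoring_times(rng, n: int) -> np.ndarray:
    kappa = rng.random(n) < 0.9
    u = rng.uniform(0.0, 4.0, n)
    return np.where(kappa, u, 4.0)


def _attendance(rng, Y: np.ndarray, W: np.ndarray, pv: tuple) -> np.ndarray:
    p = np.where(W == 1, pv[1], pv[0])
    zeta = rng.random((Y.size, VISIT_SCHEDULE.size)) < p[:, None]
    return ((Y[:, None] >= VISIT_SCHEDULE[None, :]) & zeta).astype(int)


def simulate_setup1(n: int, seed=None, tau: float = 0.5,
                    visit_probabilities: tuple = (0.75, 0.9)) -> SimulationResult:
    """Exponential failure times, non-informative Unif(-1, 1) biomarker."""
    if n < 2:
        raise ValueError("n must be at least 2")
    rng = _rng(seed)
    W = (rng.random(n) < 0.5).astype(int)
    rate = np.where(W == 1, _SETUP1_RATES[1], _SETUP1_RATES[0])
    T = rng.standard_exponential(n) / rate
    C = _censoring_times(rng, n)
    Y = np.minimum(T, C)
    eta = _attendance(rng, Y, W, visit_probabilities)
    Z = rng.uniform(-1.0, 1.0, (n, VISIT_SCHEDULE.size))
    return SimulationResult(setup="I", tau=tau, truth=TruthFunctions("I", tau),
                            T=T, C=C, W=W, eta=eta, Z=Z)


def _z_path(setup: str, tau: float, lam: np.ndarray, t) -> np.ndarray:
    t = np.asarray(t, dtype=float)
    core = np.log(np.sqrt(-np.log1p(-tau) / (lam * t ** 2) + 1.0) - 1.0)
    if setup == "II":
        return core / np.sqrt(t)
    return core / (0.1 * (t + 1.0) ** 2 + 0.1 / t)


def _simulate_weibull(setup: str, n: int, tau: float, seed,
                      visit_probabilities: tuple) -> SimulationResult:
    if n < 2:
        raise ValueError("n must be at least 2")
    rng = _rng(seed)
    W = (rng.random(n) < 0.5).astype(int)
    lam = rng.uniform(0.5, 1.5, n)
    # inversion for survival S(t) = exp(-lambda t^2)
    T = np.sqrt(rng.standard_exponential(n) / lam)
    C = _censoring_times(rng, n)
    Y = np.minimum(T, C)
    eta = _attendance(rng, Y, W, visit_probabilities)
    Z = np.column_stack([_z_path(setup, tau, lam, t) for t in VISIT_SCHEDULE])
    return SimulationResult(setup=setup, tau=tau, truth=TruthFunctions(setup, tau),
                            T=T, C=C, W=W, eta=eta, Z=Z, lam=lam)


def simulate_setup2(n: int, tau: float = 0.5, seed=None,
                    visit_probabilities: tuple = (0.5, 0.7)) -> SimulationResult:
    """Weibull(shape 2) failure times with informative biomarker."""
    if not 0 < tau < 1:
        raise ValueError("tau must lie in (0, 1)")
    return _simulate_weibull("II", n, tau, seed, visit_probabilities)


def simulate_setup3(n: int, tau: float = 0.5, seed=None,
                    visit_probabilities: tuple = (0.5, 0.7)) -> SimulationResult:
    """Setup II's cohort with the misspecified-coefficient biomarker scaling."""
    if not 0 < tau < 1:
        raise ValueError("tau must lie in (0, 1)")
    return _simulate_weibull("III", n, tau, seed, visit_probabilities)


def simulate(config: SimulationConfig, seed=None) -> SimulationResult:
    """Dispatch on config.setup."""
    seed = config.seed if seed is None else seed
    pv = config.visit_probabilities
    if config.setup == "I":
        return simulate_setup1(config.n, seed=seed, tau=config.tau,
                               visit_probabilities=pv or (0.75, 0.9))
    fn = simulate_setup2 if config.setup == "II" else simulate_setup3
    return fn(config.n, tau=config.tau, seed=seed,
              visit_probabilities=pv or (0.5, 0.7))


def _rep_rng(seed: int, rep: int, stream: int = 0) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([seed, rep, stream]))


def _fit(sim: SimulationResult, config: SimulationConfig, basis: BasisSet):
    smoothing = SmoothingConfig(scale=config.smoothing_scale)
    if config.estimator == "induced_smooth":
        return induced_smoothing_estimate(sim.data, config.tau, basis,
                                          smoothing=smoothing)
    if config.estimator == "nonsmooth":
        return nonsmooth_estimate(sim.data, config.tau, basis)
    raise ValueError(f"unknown estimator {config.estimator!r}")


def run_simulation_study(config: SimulationConfig,
                         progress: Callable[[int], None] | None = None) -> pd.DataFrame:
    """Replication study: per (tau, t, coefficient) TRUE, EB, ESE and ASE.

    EB is the mean estimate minus the truth, ESE the standard deviation of
    the estimates across replications, and ASE the mean of the delta-method
    standard errors (NaN when ``config.K == 0``, which skips variance
    estimation).  Aborts if more than 5% of replications fail to converge.
    """
    if config.replications < 2:
        raise ValueError("at least 2 replications are required")
    basis = config.basis or fractional_polynomial_basis()
    times = np.asarray(config.evaluation_times, float)
    names = ["alpha0", "alpha1", "beta1"]
    estimates = []        # (rep, coefficient, time)
    ses = []
    n_fail = 0
    for rep in range(config.replications):
        sim = simulate(config, seed=_rep_rng(config.seed, rep))
        fit = _fit(sim, config, basis)
        if not fit.converged:
            n_fail += 1
            if n_fail > 0.05 * config.replications:
                raise RuntimeError(
                    f"estimator failed to converge in {n_fail} of "
                    f"{rep + 1} replications (> 5%); last message: {fit.message}"
                )
            continue
        funcs = fit.coefficients(times)
        estimates.append(np.stack([funcs[nm].values for nm in names]))
        if config.K > 0:
            seed_k = int(_rep_rng(config.seed, rep, stream=1).integers(2 ** 31))
            comp = estimate_variance(fit, K=config.K, seed=seed_k)
            se = coefficient_function_se(comp.Sigma, basis, times,
                                         p=1, q=1)
            ses.append(np.stack([se[nm]["se"] for nm in names]))
        if progress is not None:
            progress(rep)
    est = np.stack(estimates)                      # (R, 3, T)
    se_arr = np.stack(ses) if ses else None
    truth = np.stack(true_coefficients(config.setup, config.tau, times))  # (3, T)
    rows = []
    for ci, nm in enumerate(names):
        for ti, t in enumerate(times):
            rows.append({
                "tau": config.tau,
                "t": float(t),
                "coefficient": nm,
                "TRUE": float(truth[ci, ti]),
                "EB": float(est[:, ci, ti].mean() - truth[ci, ti]),
                "ESE": float(est[:, ci, ti].std(ddof=1)),
                "ASE": float(se_arr[:, ci, ti].mean()) if se_arr is not None else np.nan,
                "n_replications": est.shape[0],
            })
    return pd.DataFrame(rows)


def run_prediction_study(config: SimulationConfig,
                         times=_DEFAULT_EVAL_TIMES,
                         L_quantile: float = 0.95) -> pd.DataFrame:
    """Dynamic-prediction experiment on Setup II.

    Per replication: fit on an independent training cohort of size
    ``config.n``, generate a test cohort of size ``config.n_test``, predict
    residual lives at each time, and score MAE_p and the truncated IPCW
    C-index.  L is the upper-``(1 - L_quantile)`` point of the test-set
    censoring times.
    """
    if config.setup != "II":
        raise ValueError("the prediction study is defined on Setup II")
    basis = config.basis or fractional_polynomial_basis()
    rows = []
    for rep in range(config.replications):
        train = simulate(config, seed=_rep_rng(config.seed, rep))
        fit = _fit(train, config, basis)
        if not fit.converged:
            warnings.warn(f"replication {rep}: fit did not converge; skipped",
                          RuntimeWarning)
            continue
        test = simulate_setup2(config.n_test, tau=config.tau,
                               seed=_rep_rng(config.seed, rep, stream=2),
                               visit_probabilities=config.visit_probabilities or (0.5, 0.7))
        L = float(np.quantile(test.C, L_quantile))
        G_test = fit_censoring_km((test.Y, test.delta))
        for t in np.asarray(times, float):
            z_t = test.z_at(t)
            preds_all = np.exp(
                fit.gamma.values @ _design_rows(fit.basis, t, test.W, z_t).T
            )
            m = mae_p(test.T, preds_all, t, L)
            at_risk = test.Y > t
            c = c_index(test.Y[at_risk], test.delta[at_risk],
                        preds_all[at_risk], G_test, t, L)
            rows.append({"tau": config.tau, "t": float(t), "rep": rep,
                         "MAE_p": m, "C_index": c, "L": L})
    return pd.DataFrame(rows)


def _design_rows(basis: BasisSet, t: float, W: np.ndarray, z: np.ndarray) -> np.ndarray:
    xi = basis.evaluate(float(t))
    x = np.column_stack([np.ones_like(W, dtype=float), W.astype(float), z])
    return (x[:, :, None] * xi[None, None, :]).reshape(x.shape[0], -1)
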