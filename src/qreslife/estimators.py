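"""Point estimation for the quantile residual-life regression model.

Two estimators of the stacked basis-coefficient vector gamma are provided.

The nonsmooth estimator solves the IPCW estimating equation

    S(gamma) = (1/n) sum_i sum_j eta_ij I(Y_i > t_j) U_ij
               { I(log(Y_i - t_j) <= gamma' U_ij) delta_i G(t_j)/G(Y_i) - tau }

by minimizing the equivalent weighted-L1 objective

    sum_ij (w_ij/n) |log(Y_i - t_j) - gamma' U_ij|
      + |M - gamma' c_minus| + |M - gamma' c_plus|

with two pseudo-observations at an extremely large response M, where
c_minus = -(1/n) sum_ij U_ij w_ij and c_plus = (2 tau / n) sum_ij U_ij
eta_ij I(Y_i > t_j).  The subgradient of this objective equals twice the
estimating function, so the L1 minimizer is the estimating-equation root.
The minimization is an exact linear program (solved with HiGHS).

The induced-smoothed estimator replaces the indicator by a normal CDF,

    I(r <= gamma'U)  ->  Phi((gamma'U - r) / sqrt(U' H U)),

with a smoothing matrix H of order 1/n (default H = I_d / n).  The smoothed
equation is continuously differentiable and is solved by damped Newton
iteration on its analytic Jacobian, started at the nonsmooth estimate.
Both estimators share the same root asymptotically.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, sparse
from scipy.stats import norm

from .basis import BasisSet, GammaVector
from .censoring import CensoringSurvival, evaluate_G, fit_censoring_km

__all__ = [
    "SmoothingConfig",
    "EstimatorControl",
    "FitResult",
    "TermTable",
    "nonsmooth_estimating_function",
    "nonsmooth_estimate",
    "smoothed_estimating_function",
    "induced_smoothing_estimate",
]


@dataclass
class SmoothingConfig:
    """Induced-smoothing bandwidth matrix H.

    ``H = scale / n * I_d`` by default; a full symmetric positive-definite
    matrix may be supplied instead.  The norm of H must shrink like 1/n for
    the smoothed and nonsmooth estimators to share their limit law.
    """

    scale: float = 1.0
    H: np.ndarray | None = None

    def matrix(self, n: int, d: int) -> np.ndarray:
        if self.H is not None:
            H = np.asarray(self.H, dtype=float)
            if H.shape != (d, d):
                raise ValueError(f"H must be {d}x{d}")
            if not np.allclose(H, H.T):
                raise ValueError("H must be symmetric")
            return H
        return (self.scale / n) * np.eye(d)


@dataclass
class EstimatorControl:
    """Solver knobs for both estimators."""

    M: float = 1e6
    max_iterations: int = 100
    tol: float = 1e-8          # convergence on the sup-norm of the EE
    step_tol: float = 1e-12    # convergence on the Newton step size
    max_halvings: int = 20
    condition_limit: float = 1e12
    initializer: str = "nonsmooth"   # or "zero"


@dataclass
class FitResult:
    """An estimated gamma with its provenance and convergence diagnostics."""

    gamma: GammaVector
    tau: float
    method: str                      # "nonsmooth" or "induced_smooth"
    converged: bool
    ef_norm: float
    n_iterations: int
    basis: BasisSet
    H: np.ndarray | None = None
    G: CensoringSurvival | None = None
    data: object = field(default=None, repr=False)
    message: str = ""

    def coefficients(self, times, covariance=None):
        from .basis import evaluate_coefficient_functions

        return evaluate_coefficient_functions(
            self.gamma, self.basis, times, tau=self.tau, covariance=covariance
        )

    def predict_residual_life(self, W, Z_at_t, t):
        from .prediction import predict_residual_life

        return predict_residual_life(self, W, Z_at_t, t)

    def to_json(self, path=None) -> str:
        payload = {
            "schema": "qreslife.fit/1",
            "gamma": self.gamma.values.tolist(),
            "p": self.gamma.p,
            "q": self.gamma.q,
            "n_basis": self.gamma.n_basis,
            "tau": self.tau,
            "method": self.method,
            "basis": {
                "kind": self.basis.kind,
                "terms": list(self.basis.terms),
                "knots": list(self.basis.knots),
                "degree": self.basis.degree,
            },
            "H_scale_trace": None if self.H is None else float(np.trace(self.H)),
            "convergence": {
                "converged": bool(self.converged),
                "ef_norm": float(self.ef_norm),
                "n_iterations": int(self.n_iterations),
                "message": self.message,
            },
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, path) -> "FitResult":
        with open(path) as fh:
            payload = json.load(fh)
        if payload.get("schema") != "qreslife.fit/1":
            raise ValueError("not a qreslife fit artifact")
        basis = BasisSet(
            kind=payload["basis"]["kind"],
            terms=tuple(payload["basis"]["terms"]),
            knots=tuple(payload["basis"]["knots"]),
            degree=payload["basis"]["degree"],
        )
        gamma = GammaVector(
            np.asarray(payload["gamma"]), payload["p"], payload["q"], payload["n_basis"]
        )
        conv = payload["convergence"]
        return cls(
            gamma=gamma, tau=payload["tau"], method=payload["method"],
            converged=conv["converged"], ef_norm=conv["ef_norm"],
            n_iterations=conv["n_iterations"], basis=basis,
            message=conv.get("message", ""),
        )


class TermTable:
    """Flattened (subject, visit) terms entering the estimating functions.

    One row per (i, j) with eta_ij = 1 and Y_i > t_j, carrying the design
    row U_ij, the log residual time r_ij = log(Y_i - t_j), the subject's
    event indicator, and the times needed to evaluate Ĝ ratios.
    """

    def __init__(self, data, basis: BasisSet):
        Y, delta, W, eta, Z = data.Y, data.delta, data.W, data.eta, data.Z
        sched = data.visit_schedule
        mask = (eta == 1) & (Y[:, None] > sched[None, :])
        self.i, self.j = np.nonzero(mask)
        self.n = data.n
        self.tvisit = sched[self.j]
        self.y = Y[self.i]
        self.delta = delta[self.i].astype(float)
        self.r = np.log(self.y - self.tvisit)
        xi_grid = basis.evaluate(sched)          # (D, L+1)
        x_full = np.concatenate(
            [np.ones((self.i.size, 1)), W[self.i], Z[self.i, self.j]], axis=1
        )                                         # (m, 1+p+q)
        Xi = xi_grid[self.j]                      # (m, L+1)
        self.U = (x_full[:, :, None] * Xi[:, None, :]).reshape(self.i.size, -1)
        if not np.all(np.isfinite(self.U)):
            raise ValueError("non-finite design rows; check covariates and basis")
        self.d = self.U.shape[1]
        self.p, self.q = data.p, data.q
        self.n_basis = basis.n_basis

    @property
    def m(self) -> int:
        return self.i.size

    def g_ratio(self, G: CensoringSurvival) -> np.ndarray:
        """delta_i Ĝ(t_j)/Ĝ(Y_i) per term; degenerate terms dropped to 0
        with a warning."""
        out = np.zeros(self.m)
        ev = self.delta == 1
        if np.any(ev):
            g_y = evaluate_G(G, self.y[ev])
            g_t = evaluate_G(G, self.tvisit[ev])
            bad = g_y == 0.0
            if np.any(bad):
                warnings.warn(
                    f"dropping {int(bad.sum())} subject-visit terms with "
                    "Ĝ(Y) = 0 (failures beyond the largest censoring time)",
                    RuntimeWarning,
                )
            ratio = np.zeros(g_y.size)
            ratio[~bad] = g_t[~bad] / g_y[~bad]
            out[ev] = ratio
        return out

    def sigma(self, H: np.ndarray) -> np.ndarray:
        """Per-term smoothing scale sqrt(U' H U) (must be positive)."""
        s2 = np.einsum("ij,jk,ik->i", self.U, H, self.U)
        if np.any(s2 <= 0):
            raise ValueError("U' H U <= 0 for some term; H must be positive definite")
        return np.sqrt(s2)


def _as_gamma_values(gamma, terms: TermTable) -> np.ndarray:
    if isinstance(gamma, GammaVector):
        return gamma.values
    g = np.asarray(gamma, dtype=float)
    if g.size != terms.d:
        raise ValueError(f"gamma has length {g.size}, expected {terms.d}")
    return g


def _check_tau(tau: float):
    if not 0.0 < tau < 1.0:
        raise ValueError(f"tau must lie strictly inside (0, 1); got {tau}")


def _nonsmooth_ef(gamma: np.ndarray, terms: TermTable, tau: float,
                  g_ratio: np.ndarray) -> np.ndarray:
    ind = (terms.r <= terms.U @ gamma).astype(float)
    return terms.U.T @ (ind * g_ratio - tau) / terms.n


def _smoothed_ef(gamma: np.ndarray, terms: TermTable, tau: float,
                 g_ratio: np.ndarray, sigma: np.ndarray) -> np.ndarray:
    z = (terms.U @ gamma - terms.r) / sigma
    return terms.U.T @ (norm.cdf(z) * g_ratio - tau) / terms.n


def _slope(gamma: np.ndarray, terms: TermTable, g_ratio: np.ndarray,
           sigma: np.ndarray) -> np.ndarray:
    z = (terms.U @ gamma - terms.r) / sigma
    coef = g_ratio * norm.pdf(z) / sigma
    return (terms.U * coef[:, None]).T @ terms.U / terms.n


def nonsmooth_estimating_function(gamma, data, tau: float, basis: BasisSet,
                                  G: CensoringSurvival) -> np.ndarray:
    """Evaluate the nonsmooth IPCW estimating function at gamma."""
    _check_tau(tau)
    terms = TermTable(data, basis)
    return _nonsmooth_ef(_as_gamma_values(gamma, terms), terms, tau, terms.g_ratio(G))


def smoothed_estimating_function(gamma, data, tau: float, basis: BasisSet,
                                 G: CensoringSurvival,
                                 smoothing: SmoothingConfig | None = None) -> np.ndarray:
    """Evaluate the induced-smoothed estimating function at gamma."""
    _check_tau(tau)
    terms = TermTable(data, basis)
    smoothing = smoothing or SmoothingConfig()
    H = smoothing.matrix(terms.n, terms.d)
    return _smoothed_ef(_as_gamma_values(gamma, terms), terms, tau,
                        terms.g_ratio(G), terms.sigma(H))


def _collinearity_report(Uw: np.ndarray, terms: TermTable) -> str:
    names = [f"alpha{j}" for j in range(terms.p + 1)] + [
        f"beta{k}" for k in range(1, terms.q + 1)
    ]
    nb = terms.n_basis
    msgs = []
    for idx, name in enumerate(names):
        block = Uw[:, idx * nb:(idx + 1) * nb]
        if np.linalg.matrix_rank(block) < min(block.shape):
            msgs.append(name)
    return ", ".join(msgs) if msgs else "cross-block collinearity"


def _solve_l1_lp(X: np.ndarray, y: np.ndarray, c_weights: np.ndarray,
                 control: EstimatorControl) -> np.ndarray:
    """Exact LP for weighted L1 regression: min sum c_k |y_k - X_k gamma|.

    Splits each residual into positive/negative parts; equality constraints
    X gamma + u - v = y with u, v >= 0.
    """
    m, d = X.shape
    A_eq = sparse.hstack(
        [sparse.csr_matrix(X), sparse.eye(m, format="csr"),
         -sparse.eye(m, format="csr")], format="csr"
    )
    cost = np.concatenate([np.zeros(d), c_weights, c_weights])
    bounds = [(None, None)] * d + [(0, None)] * (2 * m)
    res = optimize.linprog(cost, A_eq=A_eq, b_eq=y, bounds=bounds, method="highs")
    if res.status == 3:
        raise RuntimeError(
            "L1 linear program unbounded; increase M or reduce the basis size"
        )
    if not res.success:
        raise RuntimeError(f"L1 linear program failed: {res.message}")
    return res.x[:d]


def nonsmooth_estimate(data, tau: float, basis: BasisSet,
                       control: EstimatorControl | None = None,
                       G: CensoringSurvival | None = None) -> FitResult:
    """Nonsmooth IPCW estimator via exact weighted-L1 linear programming."""
    _check_tau(tau)
    control = control or EstimatorControl()
    if G is None:
        G = fit_censoring_km(data)
    terms = TermTable(data, basis)
    g_ratio = terms.g_ratio(G)
    w = g_ratio  # w_ij = eta delta I(Y>t) G(t)/G(Y); eta/I already in the table
    pos = w > 0
    if not np.any(pos):
        raise ValueError("no subject-visit term has a positive IPCW weight")
    Xw = terms.U[pos]
    if np.linalg.matrix_rank(Xw) < terms.d:
        raise np.linalg.LinAlgError(
            "stacked design is rank deficient; collinear blocks: "
            + _collinearity_report(terms.U, terms)
        )
    # data rows with weight w/n, plus the two pseudo-observations at M
    c_minus = -(terms.U * w[:, None]).sum(axis=0) / terms.n
    c_plus = 2.0 * tau * terms.U.sum(axis=0) / terms.n
    X = np.vstack([Xw, c_minus, c_plus])
    y = np.concatenate([terms.r[pos], [control.M, control.M]])
    cw = np.concatenate([w[pos] / terms.n, [1.0, 1.0]])
    gamma_hat = _solve_l1_lp(X, y, cw, control)
    ef = _nonsmooth_ef(gamma_hat, terms, tau, g_ratio)
    gamma = GammaVector(gamma_hat, terms.p, terms.q, terms.n_basis)
    return FitResult(
        gamma=gamma, tau=tau, method="nonsmooth", converged=True,
        ef_norm=float(np.max(np.abs(ef))), n_iterations=1, basis=basis,
        G=G, data=data, message="exact LP solution",
    )


def induced_smoothing_estimate(data, tau: float, basis: BasisSet,
                               control: EstimatorControl | None = None,
                               smoothing: SmoothingConfig | None = None,
                               G: CensoringSurvival | None = None) -> FitResult:
    """Induced-smoothed estimator: damped Newton on the smoothed equation.

    Initialized at the nonsmooth LP estimate by default.  Returns a
    ``FitResult`` with ``converged=False`` (never a silent success) if the
    iteration stalls.
    """
    _check_tau(tau)
    control = control or EstimatorControl()
    smoothing = smoothing or SmoothingConfig()
    if G is None:
        G = fit_censoring_km(data)
    terms = TermTable(data, basis)
    g_ratio = terms.g_ratio(G)
    H = smoothing.matrix(terms.n, terms.d)
    sigma = terms.sigma(H)

    if control.initializer == "nonsmooth":
        gamma = nonsmooth_estimate(data, tau, basis, control, G).gamma.values.copy()
    elif control.initializer == "zero":
        gamma = np.zeros(terms.d)
    else:
        raise ValueError(f"unknown initializer {control.initializer!r}")

    S = _smoothed_ef(gamma, terms, tau, g_ratio, sigma)
    n_iter = 0
    message = ""
    converged = False
    for n_iter in range(1, control.max_iterations + 1):
        if np.max(np.abs(S)) <= control.tol:
            converged = True
            break
        A = _slope(gamma, terms, g_ratio, sigma)
        cond = np.linalg.cond(A)
        if not np.isfinite(cond) or cond > control.condition_limit:
            # derivative-free polish when the slope is ill-conditioned
            sol = optimize.root(
                lambda g: _smoothed_ef(g, terms, tau, g_ratio, sigma),
                gamma, method="hybr",
            )
            gamma = sol.x
            S = _smoothed_ef(gamma, terms, tau, g_ratio, sigma)
            message = f"ill-conditioned slope (cond={cond:.2e}); hybr polish"
            converged = bool(np.max(np.abs(S)) <= control.tol)
            break
        step = np.linalg.solve(A, S)
        lam, norm0 = 1.0, np.linalg.norm(S)
        for _ in range(control.max_halvings):
            trial = gamma - lam * step
            S_trial = _smoothed_ef(trial, terms, tau, g_ratio, sigma)
            if np.linalg.norm(S_trial) < norm0:
                break
            lam *= 0.5
        if np.max(np.abs(lam * step)) < control.step_tol:
            message = "step size below tolerance"
            gamma, S = trial, S_trial
            converged = bool(np.max(np.abs(S)) <= control.tol)
            break
        gamma, S = trial, S_trial
    else:
        message = f"no convergence in {control.max_iterations} iterations"
    if converged and not message:
        message = "Newton iteration converged"

    return FitResult(
        gamma=GammaVector(gamma, terms.p, terms.q, terms.n_basis),
        tau=tau, method="induced_smooth", converged=converged,
        ef_norm=float(np.max(np.abs(S))), n_iterations=n_iter, basis=basis,
        H=H, G=G, data=data, message=message,
    )
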