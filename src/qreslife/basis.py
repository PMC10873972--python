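"""Basis-function machinery for time-varying regression coefficients.

The quantile residual-life model

    log Q_{T-t}(tau | T >= t, W, Z(t)) = alpha(tau, t)' W + beta(tau, t)' Z(t)

restricts each time-varying coefficient to a linear combination of L+1
predefined basis functions f_0(t), ..., f_L(t):

    alpha_j(t) = sum_l a_{j,l} f_l(t),    beta_k(t) = sum_l b_{k,l} f_l(t).

Two basis families are supported: fractional polynomials (powers and logs
of t, the default being {1, log t, sqrt t, 1/sqrt t}) and cubic B-splines.
The stacked coefficient vector gamma holds the blocks
(a_0, a_1, ..., a_p, b_1, ..., b_q), each of length L+1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.interpolate import BSpline

__all__ = [
    "BasisSet",
    "GammaVector",
    "CoefficientFunction",
    "fractional_polynomial_basis",
    "bspline_basis",
    "basis_preset",
    "evaluate_basis",
    "build_design_row",
    "evaluate_coefficient_functions",
]


class BasisDomainError(ValueError):
    """Evaluation time lies outside the basis domain."""


# fractional-polynomial term vocabulary: name -> (function, needs t > 0)
_FP_TERMS = {
    "1": (lambda t: np.ones_like(t), False),
    "log": (np.log, True),
    "sqrt": (np.sqrt, False),
    "invsqrt": (lambda t: 1.0 / np.sqrt(t), True),
    "inv": (lambda t: 1.0 / t, True),
    "t": (lambda t: t, False),
    "t2": (np.square, False),
}


@dataclass(frozen=True)
class BasisSet:
    """A set of L+1 basis functions f_0..f_L with shared domain.

    Parameters
    ----------
    kind :
        ``"fractional_polynomial"`` or ``"bspline"``.
    terms :
        For fractional polynomials, the term names (keys of the term
        vocabulary).  Empty for B-splines.
    knots, degree :
        Full (padded) knot vector and degree for B-splines.  Unused for
        fractional polynomials.
    """

    kind: str
    terms: tuple[str, ...] = ()
    knots: tuple[float, ...] = ()
    degree: int = 3

    @property
    def n_basis(self) -> int:
        if self.kind == "fractional_polynomial":
            return len(self.terms)
        return len(self.knots) - self.degree - 1

    @property
    def domain_min(self) -> float:
        """Smallest t at which every term is finite.

        Terms log t, 1/sqrt(t) and 1/t diverge at 0, so the fractional
        default requires strictly positive times (the smallest positive
        normal float in practice).
        """
        if self.kind == "fractional_polynomial":
            if any(_FP_TERMS[name][1] for name in self.terms):
                return float(np.finfo(float).tiny)
            return 0.0
        return float(self.knots[self.degree])

    def evaluate(self, t: float | np.ndarray) -> np.ndarray:
        """Evaluate (f_0(t), ..., f_L(t)).

        Scalar ``t`` gives a vector of length L+1; an array of shape (m,)
        gives an (m, L+1) matrix.
        """
        t_arr = np.asarray(t, dtype=float)
        scalar = t_arr.ndim == 0
        t_arr = np.atleast_1d(t_arr)
        if self.kind == "fractional_polynomial":
            for name in self.terms:
                if _FP_TERMS[name][1] and np.any(t_arr <= 0):
                    bad = float(t_arr[t_arr <= 0][0])
                    raise BasisDomainError(
                        f"basis term {name!r} is undefined at t = {bad}; "
                        "evaluation requires t > 0"
                    )
            cols = [_FP_TERMS[name][0](t_arr) for name in self.terms]
            out = np.column_stack(cols)
        elif self.kind == "bspline":
            kn = np.asarray(self.knots)
            lo, hi = kn[self.degree], kn[-self.degree - 1]
            if np.any(t_arr < lo) or np.any(t_arr > hi):
                raise BasisDomainError(
                    f"B-spline basis defined on [{lo}, {hi}]; got t outside"
                )
            out = BSpline.design_matrix(t_arr, kn, self.degree).toarray()
        else:  # pragma: no cover - guarded at construction
            raise ValueError(f"unknown basis kind {self.kind!r}")
        if not np.all(np.isfinite(out)):
            raise BasisDomainError("basis evaluation produced non-finite values")
        return out[0] if scalar else out


def fractional_polynomial_basis(terms: Sequence[str] = ("1", "log", "sqrt", "invsqrt")) -> BasisSet:
    """Fractional-polynomial basis from term names.

    The default set {1, log t, sqrt t, 1/sqrt t} is the standard choice for
    residual-life coefficient functions.
    """
    unknown = [x for x in terms if x not in _FP_TERMS]
    if unknown:
        raise ValueError(f"unknown fractional-polynomial terms: {unknown}")
    return BasisSet(kind="fractional_polynomial", terms=tuple(terms))


def bspline_basis(
    domain: tuple[float, float],
    n_interior_knots: int = 0,
    degree: int = 3,
) -> BasisSet:
    """Cubic (by default) B-spline basis with equally spaced interior knots."""
    lo, hi = float(domain[0]), float(domain[1])
    if not hi > lo:
        raise ValueError("domain must satisfy hi > lo")
    interior = np.linspace(lo, hi, n_interior_knots + 2)[1:-1]
    knots = np.concatenate([[lo] * (degree + 1), interior, [hi] * (degree + 1)])
    return BasisSet(kind="bspline", knots=tuple(knots), degree=degree)


#: named presets mirroring the simulation study's basis choices
_PRESETS = {
    "fp": ("1", "log", "sqrt", "invsqrt"),
    "fp5": ("1", "log", "sqrt", "invsqrt", "inv"),
    "fp_alt": ("1", "invsqrt", "t", "t2"),
}


def basis_preset(name: str, domain: tuple[float, float] = (0.1, 1.0)) -> BasisSet:
    """Look up a basis by preset name.

    ``fp`` (default fractional polynomial), ``fp5``, ``fp_alt``, or
    ``bspline0``/``bspline1``/``bspline2`` (cubic with that many interior
    knots on ``domain``).
    """
    if name in _PRESETS:
        return fractional_polynomial_basis(_PRESETS[name])
    if name.startswith("bspline"):
        return bspline_basis(domain, n_interior_knots=int(name[len("bspline"):] or 0))
    raise ValueError(f"unknown basis preset {name!r}")


def evaluate_basis(basis: BasisSet, t: float | np.ndarray) -> np.ndarray:
    """Functional alias for :meth:`BasisSet.evaluate`."""
    return basis.evaluate(t)


@dataclass(frozen=True)
class GammaVector:
    """Stacked coefficient vector with block layout.

    ``values`` has length d = (p+1+q)(L+1) and is laid out as the
    concatenation of per-coefficient blocks
    (a_{0,0..L}, ..., a_{p,0..L}, b_{1,0..L}, ..., b_{q,0..L}).
    """

    values: np.ndarray
    p: int
    q: int
    n_basis: int

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if v.ndim != 1 or v.size != self.d:
            raise ValueError(
                f"gamma length {v.size} does not match (p+1+q)(L+1) = {self.d}"
            )

    @property
    def d(self) -> int:
        return (self.p + 1 + self.q) * self.n_basis

    @property
    def n_coefficients(self) -> int:
        return self.p + 1 + self.q

    @property
    def coefficient_names(self) -> list[str]:
        return [f"alpha{j}" for j in range(self.p + 1)] + [
            f"beta{k}" for k in range(1, self.q + 1)
        ]

    def block(self, index: int) -> np.ndarray:
        """Basis-coefficient block for the ``index``-th coefficient function
        (0..p are alpha blocks; p+1..p+q are beta blocks)."""
        if not 0 <= index < self.n_coefficients:
            raise IndexError(f"coefficient index {index} out of range")
        s = index * self.n_basis
        return self.values[s : s + self.n_basis]

    def entry(self, coefficient: int, basis_index: int) -> float:
        if not 0 <= basis_index < self.n_basis:
            raise IndexError(f"basis index {basis_index} out of range")
        return float(self.block(coefficient)[basis_index])

    @classmethod
    def from_blocks(cls, blocks: Sequence[np.ndarray], p: int, q: int) -> "GammaVector":
        if len(blocks) != p + 1 + q:
            raise ValueError("expected p+1+q blocks")
        n_basis = len(blocks[0])
        return cls(np.concatenate([np.asarray(b, float) for b in blocks]), p, q, n_basis)

    @classmethod
    def zeros(cls, p: int, q: int, n_basis: int) -> "GammaVector":
        return cls(np.zeros((p + 1 + q) * n_basis), p, q, n_basis)


def build_design_row(subject, visit_index: int, basis: BasisSet, visit_schedule) -> np.ndarray:
    """Design row U_i(t_j) = (xi(t_j), W_1 xi(t_j), ..., Z_q(t_j) xi(t_j)).

    Requires the visit to be attended and the observed time to exceed the
    visit time (otherwise the term does not enter the estimating function).
    """
    t_j = float(np.asarray(visit_schedule)[visit_index])
    if not subject.visit_attended[visit_index]:
        raise ValueError(
            f"subject {subject.subject_id!r} did not attend visit {visit_index}"
        )
    if not subject.observed_time > t_j:
        raise ValueError(
            f"observed time {subject.observed_time} <= visit time {t_j}; "
            "no residual life to model at this visit"
        )
    xi = basis.evaluate(t_j)
    z = np.asarray(subject.covariates_varying[visit_index], dtype=float)
    x = np.concatenate([[1.0], np.asarray(subject.covariates_fixed, float), z])
    return np.kron(x, xi)


@dataclass
class CoefficientFunction:
    """Pointwise values of one estimated coefficient function.

    When a covariance is supplied, carries delta-method standard errors and
    Wald 95% pointwise confidence limits (estimate +/- 1.96 SE).
    """

    name: str
    tau: float | None
    times: np.ndarray
    values: np.ndarray
    se: np.ndarray | None = None
    ci_lower: np.ndarray | None = field(default=None)
    ci_upper: np.ndarray | None = field(default=None)


_Z975 = 1.959963984540054


def evaluate_coefficient_functions(
    gamma: GammaVector,
    basis: BasisSet,
    times,
    tau: float | None = None,
    covariance: np.ndarray | None = None,
) -> dict[str, CoefficientFunction]:
    """Evaluate alpha_j(t) and beta_k(t) by block inner products.

    ``covariance`` is an optional d x d covariance of gamma; its (L+1)-sized
    diagonal blocks give SE(alpha_j(t)) = sqrt(xi(t)' Sigma_jj xi(t)).
    """
    times = np.atleast_1d(np.asarray(times, dtype=float))
    Xi = basis.evaluate(times)  # (m, L+1)
    out: dict[str, CoefficientFunction] = {}
    nb = gamma.n_basis
    for idx, name in enumerate(gamma.coefficient_names):
        vals = Xi @ gamma.block(idx)
        se = ci_lo = ci_hi = None
        if covariance is not None:
            s = idx * nb
            block = np.asarray(covariance)[s : s + nb, s : s + nb]
            var = np.einsum("ij,jk,ik->i", Xi, block, Xi)
            se = np.sqrt(np.maximum(var, 0.0))
            ci_lo = vals - _Z975 * se
            ci_hi = vals + _Z975 * se
        out[name] = CoefficientFunction(
            name=name, tau=tau, times=times, values=vals,
            se=se, ci_lower=ci_lo, ci_upper=ci_hi,
        )
    return out
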