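"""Kaplan-Meier estimation of the censoring survival function and IPCW weights.

Right censoring biases naive residual-life quantile estimation because late
failures are under-observed.  The correction weights each uncensored
subject-visit term by the inverse of the conditional probability of remaining
uncensored, Ĝ(Y_i)/Ĝ(t_j), where G(t) = P(C > t) is estimated by the
product-limit method with the roles of failure and censoring reversed.

For the multiplier-resampling variance estimator the same product-limit
computation is re-run with positive per-subject weights theta_i (both the
event count and the risk-set size become theta-weighted sums), giving the
perturbed estimate Ĝ*.

Tie convention: failures precede censorings at a shared time, so the risk
set at a censoring jump excludes failures occurring at that same time.
Ĝ is evaluated right-continuously.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "CensoringSurvival",
    "fit_censoring_km",
    "evaluate_G",
    "ipcw_weight",
    "WeightDegeneracyError",
]


class WeightDegeneracyError(ValueError):
    """An IPCW weight would be infinite (Ĝ(Y) = 0 with a nonzero numerator)."""


@dataclass(frozen=True)
class CensoringSurvival:
    """Right-continuous step-function estimate of G(t) = P(C > t).

    ``jump_times`` are the sorted distinct censoring times at which Ĝ drops;
    ``survival_values`` are the values of Ĝ at (and after) each jump.
    Ĝ(t) = 1 for t before the first jump.
    """

    jump_times: np.ndarray
    survival_values: np.ndarray
    multiplier_weights: np.ndarray | None = None

    def __call__(self, t):
        return evaluate_G(self, t)

    def to_frame(self):
        """(jump_time, survival) pairs as a DataFrame, CSV-ready."""
        import pandas as pd

        return pd.DataFrame({
            "jump_time": self.jump_times,
            "survival": self.survival_values,
        })


def _km_censoring(Y: np.ndarray, delta: np.ndarray, theta: np.ndarray):
    """Weighted product-limit estimate treating censoring as the event.

    At a censoring time u the risk set counts subjects with Y > u plus
    censored subjects with Y == u (failures tied at u have already left).
    """
    cens = delta == 0
    if not np.any(cens):
        return np.empty(0), np.empty(0)
    u = np.unique(Y[cens])
    d = np.zeros(u.size)
    np.add.at(d, np.searchsorted(u, Y[cens]), theta[cens])
    # sum of theta over Y <= u, via sorted cumulative sums
    order = np.argsort(Y, kind="stable")
    csum = np.cumsum(theta[order])
    le_u = csum[np.searchsorted(Y[order], u, side="right") - 1]
    total = csum[-1]
    risk = total - le_u + d
    with np.errstate(invalid="ignore"):
        G = np.cumprod(1.0 - d / risk)
    return u, G


def fit_censoring_km(data, multipliers=None) -> CensoringSurvival:
    """Fit Ĝ (or its multiplier-perturbed version Ĝ*) from study data.

    ``data`` may be a :class:`~qreslife.data.StudyData` or a pair of arrays
    ``(Y, delta)``.  ``multipliers``, if given, are strictly positive
    per-subject weights theta_i.
    """
    if isinstance(data, tuple):
        Y, delta = (np.asarray(a) for a in data)
    else:
        Y, delta = data.Y, data.delta
    n = Y.size
    if n == 0:
        raise ValueError("cannot fit a censoring distribution on empty data")
    if multipliers is None:
        theta = np.ones(n)
    else:
        theta = np.asarray(multipliers, dtype=float)
        if theta.size != n:
            raise ValueError("multipliers must have one entry per subject")
        if np.any(theta <= 0):
            raise ValueError("multipliers must be strictly positive")
    jumps, surv = _km_censoring(np.asarray(Y, float), np.asarray(delta), theta)
    return CensoringSurvival(jumps, surv,
                             None if multipliers is None else theta)


def evaluate_G(G: CensoringSurvival, t):
    """Right-continuous step evaluation of Ĝ at time(s) t >= 0."""
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise ValueError("Ĝ is defined for t >= 0 only")
    if G.jump_times.size == 0:
        out = np.ones_like(t_arr)
        return float(out) if t_arr.ndim == 0 else out
    idx = np.searchsorted(G.jump_times, t_arr, side="right")
    vals = np.concatenate([[1.0], G.survival_values])[idx]
    return float(vals) if t_arr.ndim == 0 else vals


def ipcw_weight(subject, visit_index: int, G: CensoringSurvival, visit_time: float) -> float:
    """IPCW weight w_ij = eta_ij delta_i I(Y_i > t_j) Ĝ(t_j)/Ĝ(Y_i).

    Zero whenever the subject was censored, missed the visit, or had already
    left follow-up.  Raises :class:`WeightDegeneracyError` when the weight
    would be infinite.
    """
    eta = int(subject.visit_attended[visit_index])
    delta = int(subject.event_indicator)
    Y = float(subject.observed_time)
    if eta == 0 or delta == 0 or Y <= visit_time:
        return 0.0
    g_t = evaluate_G(G, visit_time)
    g_y = evaluate_G(G, Y)
    if g_y == 0.0:
        raise WeightDegeneracyError(
            f"Ĝ(Y) = 0 for subject {subject.subject_id!r} (failure beyond the "
            "largest censoring time); its weighted terms must be dropped"
        )
    return g_t / g_y
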