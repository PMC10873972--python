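"""Dynamic residual-life prediction and its accuracy measures.

From a fitted model the tau-th quantile of the remaining life at time t for
a subject with covariates (W, Z(t)) is

    Q^p = exp( alpha(tau, t)' [1, W] + beta(tau, t)' Z(t) ).

Two complementary accuracy measures are implemented:

* MAE_p (calibration): mean over subjects still at risk at t of
  |min(T - t, L - t) - Q^p|, where the *true* residual life is truncated at
  L - t (predictions are not truncated).  Requires the true failure time,
  so it is computed on simulated test sets.

* Truncated IPCW C-index (discrimination): among pairs (i, j) with i
  uncensored, 0 < Y_i - t < Y_j - t and Y_i < L, the weighted proportion
  whose predicted residual lives are ordered concordantly, with weights
  delta_i {Ĝ(Y_i)/Ĝ(t)}^-2.  Prediction ties count as discordant (strict
  inequality), and the index is invariant to strictly increasing transforms
  of the predictions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .censoring import CensoringSurvival, evaluate_G

__all__ = ["PredictionSet", "predict_residual_life", "predict_many",
           "mae_p", "c_index", "prediction_grid"]


@dataclass
class PredictionSet:
    """Predicted tau-quantile residual lives for subjects at risk at t."""

    t: float
    tau: float
    predictions: np.ndarray        # positive, one per eligible subject
    eligible: np.ndarray           # boolean mask into the originating cohort
    L_trunc: float | None = None


def _linear_predictor(fit, W, Z_at_t, t: float) -> np.ndarray:
    xi = fit.basis.evaluate(float(t))
    W = np.atleast_2d(np.asarray(W, float))
    Z = np.atleast_2d(np.asarray(Z_at_t, float))
    if W.shape[1] != fit.gamma.p or Z.shape[1] != fit.gamma.q:
        raise ValueError(
            f"covariate dimensions (p={W.shape[1]}, q={Z.shape[1]}) do not "
            f"match the fit (p={fit.gamma.p}, q={fit.gamma.q})"
        )
    x = np.hstack([np.ones((W.shape[0], 1)), W, Z])        # (m, 1+p+q)
    if not np.all(np.isfinite(x)):
        raise ValueError("covariates must be finite")
    U = (x[:, :, None] * xi[None, None, :]).reshape(x.shape[0], -1)
    return U @ fit.gamma.values


def predict_residual_life(fit, W, Z_at_t, t: float):
    """exp of the linear predictor at time t; scalar in, scalar out."""
    lp = _linear_predictor(fit, W, Z_at_t, t)
    out = np.exp(lp)
    return float(out[0]) if out.size == 1 and np.ndim(W) <= 1 else out


def predict_many(fit, W, Z_at_t, t: float, eligible=None,
                 L_trunc: float | None = None) -> PredictionSet:
    """Vectorized predictions wrapped with eligibility bookkeeping."""
    W = np.atleast_2d(np.asarray(W, float))
    if eligible is None:
        eligible = np.ones(W.shape[0], dtype=bool)
    preds = np.exp(_linear_predictor(fit, W[eligible],
                                     np.atleast_2d(np.asarray(Z_at_t, float))[eligible], t))
    return PredictionSet(t=float(t), tau=fit.tau, predictions=preds,
                         eligible=np.asarray(eligible, bool), L_trunc=L_trunc)


def mae_p(true_times, predictions, t: float, L_trunc: float) -> float:
    """Mean absolute prediction error with the truth truncated at L - t.

    ``true_times`` and ``predictions`` are aligned arrays over the same
    subjects; only subjects with T > t enter the average.
    """
    T = np.asarray(true_times, float)
    Q = np.asarray(predictions, float)
    if T.shape != Q.shape:
        raise ValueError("true_times and predictions must be aligned")
    at_risk = T > t
    if not np.any(at_risk):
        raise ValueError(f"no subject is at risk at t = {t}")
    truth = np.minimum(T[at_risk] - t, L_trunc - t)
    return float(np.mean(np.abs(truth - Q[at_risk])))


def c_index(Y, delta, predictions, G: CensoringSurvival, t: float,
            L_trunc: float, chunk: int = 512) -> float:
    """Truncated IPCW concordance index for predicted residual lives.

    ``Y``, ``delta`` and ``predictions`` are aligned over the evaluation
    cohort; ``G`` is the censoring survival estimate of that same cohort.
    Raises when no comparable pair exists.
    """
    Y = np.asarray(Y, float)
    delta = np.asarray(delta)
    P = np.asarray(predictions, float)
    if not (Y.shape == P.shape == delta.shape):
        raise ValueError("Y, delta and predictions must be aligned")
    g_t = evaluate_G(G, float(t))
    g_y = evaluate_G(G, Y)
    anchors = (delta == 1) & (Y > t) & (Y < L_trunc) & (g_y > 0)
    w = np.zeros(Y.size)
    w[anchors] = (g_y[anchors] / g_t) ** (-2.0)
    idx = np.nonzero(anchors)[0]
    num = 0.0
    den = 0.0
    for s in range(0, idx.size, chunk):
        block = idx[s:s + chunk]
        later = Y[None, :] > Y[block, None]            # I(Y_i - t < Y_j - t)
        den += float((w[block, None] * later).sum())
        conc = later & (P[None, :] > P[block, None])   # strict inequality
        num += float((w[block, None] * conc).sum())
    if den == 0.0:
        raise ValueError(
            f"no comparable pair at t = {t} with truncation L = {L_trunc}"
        )
    return num / den


def prediction_grid(fit, profiles: pd.DataFrame, times, taus=None) -> pd.DataFrame:
    """CSV-ready grid of predicted residual lives per (t, profile).

    ``profiles`` holds columns W1..Wp and Z1..Zq; Z columns are interpreted
    as the biomarker value carried at each requested time.
    """
    p, q = fit.gamma.p, fit.gamma.q
    w_cols = [f"W{k + 1}" for k in range(p)]
    z_cols = [f"Z{k + 1}" for k in range(q)]
    missing = [c for c in w_cols + z_cols if c not in profiles.columns]
    if missing:
        raise ValueError(f"profiles are missing columns {missing}")
    rows = []
    for t in np.atleast_1d(np.asarray(times, float)):
        preds = np.exp(_linear_predictor(
            fit, profiles[w_cols].to_numpy(float) if p else np.empty((len(profiles), 0)),
            profiles[z_cols].to_numpy(float) if q else np.empty((len(profiles), 0)),
            float(t)))
        for r, pred in zip(profiles.itertuples(index=False), preds):
            row = {"t": float(t), "tau": fit.tau}
            row.update({c: getattr(r, c) for c in w_cols + z_cols})
            row["predicted_residual_life"] = float(pred)
            rows.append(row)
    return pd.DataFrame(rows)
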