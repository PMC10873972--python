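"""Data model for right-censored outcomes with scheduled longitudinal covariates.

A study consists of n independent subjects.  Each subject carries an observed
follow-up time Y = min(T, C), an event indicator delta = I(T <= C), a vector
of p time-fixed covariates W (the intercept is implicit and added at design
time), and, on a shared planned visit schedule t_1 < ... < t_D, attendance
indicators eta_j and q time-varying covariate values Z(t_j) observed exactly
at attended visits.

The on-disk format is a long CSV with one row per (subject, visit):
``id, Y, delta, W1..Wp, visit_time, attended, Z1..Zq``.  Z cells are empty
when the visit was not attended.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import cached_property

import numpy as np
import pandas as pd

__all__ = ["SubjectRecord", "StudyData", "read_study_csv", "write_study_csv"]


class SchemaError(ValueError):
    """The input violates the long-format study-data schema."""


@dataclass
class SubjectRecord:
    """One subject's censored outcome, covariates and visit history.

    ``covariates_varying`` has shape (D, q) with NaN at unattended visits.
    """

    subject_id: str
    observed_time: float
    event_indicator: int
    covariates_fixed: np.ndarray
    visit_attended: np.ndarray
    covariates_varying: np.ndarray

    def __post_init__(self):
        self.covariates_fixed = np.atleast_1d(np.asarray(self.covariates_fixed, float))
        self.visit_attended = np.atleast_1d(np.asarray(self.visit_attended, int))
        self.covariates_varying = np.asarray(self.covariates_varying, float)
        if self.covariates_varying.ndim == 1:
            self.covariates_varying = self.covariates_varying[:, None]
        if not self.observed_time > 0:
            raise SchemaError(
                f"subject {self.subject_id!r}: observed time must be > 0"
            )
        if self.event_indicator not in (0, 1):
            raise SchemaError(
                f"subject {self.subject_id!r}: event indicator must be 0 or 1"
            )
        if not np.all(np.isin(self.visit_attended, (0, 1))):
            raise SchemaError(
                f"subject {self.subject_id!r}: attendance must be 0/1"
            )
        if self.covariates_varying.shape[0] != self.visit_attended.size:
            raise SchemaError(
                f"subject {self.subject_id!r}: Z rows != number of visits"
            )
        att = self.visit_attended == 1
        if not np.all(np.isfinite(self.covariates_varying[att])):
            j = int(np.nonzero(att & ~np.all(np.isfinite(self.covariates_varying), axis=1))[0][0])
            raise SchemaError(
                f"subject {self.subject_id!r}: missing Z at attended visit {j}"
            )


@dataclass
class StudyData:
    """n subjects on a shared, strictly increasing planned visit schedule."""

    subjects: list[SubjectRecord]
    visit_schedule: np.ndarray

    def __post_init__(self):
        self.visit_schedule = np.atleast_1d(np.asarray(self.visit_schedule, float))
        if len(self.subjects) == 0:
            raise SchemaError("study data must contain at least one subject")
        if np.any(self.visit_schedule <= 0) or np.any(np.diff(self.visit_schedule) <= 0):
            raise SchemaError("visit schedule must be strictly increasing and > 0")
        D = self.visit_schedule.size
        p, q = self.p, self.q
        for s in self.subjects:
            if s.visit_attended.size != D:
                raise SchemaError(f"subject {s.subject_id!r}: expected {D} visits")
            if s.covariates_fixed.size != p or s.covariates_varying.shape[1] != q:
                raise SchemaError(
                    f"subject {s.subject_id!r}: covariate dimensions do not "
                    f"match (p={p}, q={q})"
                )

    @property
    def n(self) -> int:
        return len(self.subjects)

    @property
    def p(self) -> int:
        return self.subjects[0].covariates_fixed.size

    @property
    def q(self) -> int:
        return self.subjects[0].covariates_varying.shape[1]

    @property
    def n_visits(self) -> int:
        return self.visit_schedule.size

    # stacked array views used by the vectorized estimation routines
    @cached_property
    def Y(self) -> np.ndarray:
        return np.array([s.observed_time for s in self.subjects])

    @cached_property
    def delta(self) -> np.ndarray:
        return np.array([s.event_indicator for s in self.subjects])

    @cached_property
    def W(self) -> np.ndarray:
        return np.stack([s.covariates_fixed for s in self.subjects])

    @cached_property
    def eta(self) -> np.ndarray:
        return np.stack([s.visit_attended for s in self.subjects])

    @cached_property
    def Z(self) -> np.ndarray:
        return np.stack([s.covariates_varying for s in self.subjects])

    @classmethod
    def from_arrays(cls, Y, delta, W, eta, Z, visit_schedule, ids=None) -> "StudyData":
        """Assemble from stacked arrays (shapes (n,), (n,), (n,p), (n,D), (n,D,q))."""
        Y = np.asarray(Y, float)
        n = Y.size
        ids = [str(i) for i in (ids if ids is not None else range(n))]
        W = np.asarray(W, float).reshape(n, -1)
        Z = np.asarray(Z, float)
        if Z.ndim == 2:
            Z = Z[:, :, None]
        subjects = [
            SubjectRecord(ids[i], float(Y[i]), int(delta[i]), W[i],
                          np.asarray(eta)[i], Z[i])
            for i in range(n)
        ]
        return cls(subjects, visit_schedule)


def write_study_csv(data: StudyData, path) -> None:
    """Write the long-format CSV dialect (one row per subject-visit)."""
    p, q, D = data.p, data.q, data.n_visits
    rows = []
    for s in data.subjects:
        for j in range(D):
            row = {"id": s.subject_id,
                   "Y": s.observed_time,
                   "delta": s.event_indicator}
            for k in range(p):
                row[f"W{k + 1}"] = s.covariates_fixed[k]
            row["visit_time"] = data.visit_schedule[j]
            row["attended"] = int(s.visit_attended[j])
            for k in range(q):
                z = s.covariates_varying[j, k]
                row[f"Z{k + 1}"] = z if s.visit_attended[j] else np.nan
            rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def read_study_csv(path) -> StudyData:
    """Read and validate the long-format CSV, assembling SubjectRecords."""
    df = pd.read_csv(path)
    base_cols = {"id", "Y", "delta", "visit_time", "attended"}
    missing = base_cols - set(df.columns)
    if missing:
        raise SchemaError(f"missing required columns: {sorted(missing)}")
    w_cols = sorted((c for c in df.columns if c.startswith("W") and c[1:].isdigit()),
                    key=lambda c: int(c[1:]))
    z_cols = sorted((c for c in df.columns if c.startswith("Z") and c[1:].isdigit()),
                    key=lambda c: int(c[1:]))
    schedule = np.sort(df["visit_time"].unique())
    D = schedule.size
    subjects = []
    for sid, g in df.groupby("id", sort=False):
        g = g.sort_values("visit_time")
        if g.shape[0] != D or not np.allclose(g["visit_time"].to_numpy(), schedule):
            raise SchemaError(
                f"subject {sid!r}: expected one row per scheduled visit "
                f"({D} visits)"
            )
        y_vals = g["Y"].unique()
        d_vals = g["delta"].unique()
        if y_vals.size != 1 or d_vals.size != 1:
            raise SchemaError(f"subject {sid!r}: Y/delta must be constant across rows")
        att = g["attended"].to_numpy().astype(int)
        Z = g[z_cols].to_numpy(float) if z_cols else np.empty((D, 0))
        for j in np.nonzero(att == 1)[0]:
            if z_cols and not np.all(np.isfinite(Z[j])):
                raise SchemaError(
                    f"subject {sid!r}: missing Z at attended visit {j} "
                    f"(row {int(g.index[j]) + 2} of file)"
                )
        W = g.iloc[0][w_cols].to_numpy(float) if w_cols else np.empty(0)
        try:
            subjects.append(SubjectRecord(str(sid), float(y_vals[0]), int(d_vals[0]),
                                          W, att, Z))
        except SchemaError as e:
            raise SchemaError(f"row {int(g.index[0]) + 2}: {e}") from e
    return StudyData(subjects, schedule)
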