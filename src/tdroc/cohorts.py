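"""Cohort containers, validation and delimited-text IO.

A baseline cohort holds one record per subject: the observed time
``Z = min(T, C)`` (event time ``T`` censored at ``C``), the event indicator
``delta`` (1 = event observed, 0 = censored) and a scalar marker or risk
score ``X`` for which higher values are taken as more indicative of disease.
A longitudinal cohort additionally carries, for each subject, an ascending
sequence of (visit time, marker value) pairs.

All times are carried in a single user-declared unit (days by default); no
unit conversion happens anywhere inside the library.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "BaselineCohort",
    "LongitudinalCohort",
    "CohortValidationError",
    "read_baseline",
    "write_baseline",
    "read_longitudinal",
    "write_longitudinal",
    "last_value_cohort",
    "BASELINE_COLUMNS",
    "LONGITUDINAL_COLUMNS",
]

#: default column names for baseline delimited files
BASELINE_COLUMNS = {"id": "id", "time": "time", "event": "event", "marker": "marker"}
#: default column names for longitudinal (long-format) delimited files
LONGITUDINAL_COLUMNS = {
    "id": "id",
    "visit_time": "visit_time",
    "marker": "marker",
    "time": "time",
    "event": "event",
}


class CohortValidationError(ValueError):
    """Raised when input data violate the cohort contracts."""


@dataclass(frozen=True)
class BaselineCohort:
    """(Z, delta, X) triplets with one row per subject.

    Parameters
    ----------
    subject_id : array of opaque labels, unique.
    Z : observed times, finite and strictly positive.
    delta : event indicators in {0, 1}.
    X : scalar marker or risk score.
    time_unit : label only; never interpreted.
    """

    subject_id: np.ndarray
    Z: np.ndarray
    delta: np.ndarray
    X: np.ndarray
    time_unit: str = "days"

    def __post_init__(self):
        object.__setattr__(self, "subject_id", np.asarray(self.subject_id, dtype=object))
        object.__setattr__(self, "Z", np.asarray(self.Z, dtype=float))
        object.__setattr__(self, "delta", np.asarray(self.delta, dtype=int))
        object.__setattr__(self, "X", np.asarray(self.X, dtype=float))
        n = len(self.Z)
        if not (len(self.subject_id) == len(self.delta) == len(self.X) == n):
            raise CohortValidationError("subject_id, Z, delta, X must have equal length")
        if n < 2:
            raise CohortValidationError(f"cohort needs at least 2 subjects, got {n}")
        if not np.all(np.isfinite(self.Z)) or np.any(self.Z <= 0):
            raise CohortValidationError("all observed times must be finite and > 0")
        bad = ~np.isin(self.delta, (0, 1))
        if bad.any():
            raise CohortValidationError(
                f"event indicator must be 0 or 1; offending rows {np.flatnonzero(bad).tolist()}"
            )
        if not np.all(np.isfinite(self.X)):
            raise CohortValidationError("marker values must be finite")
        if len(set(self.subject_id.tolist())) != n:
            raise CohortValidationError("subject ids must be unique")

    @property
    def n(self) -> int:
        return len(self.Z)

    @property
    def n_events(self) -> int:
        return int(self.delta.sum())

    def event_times(self) -> np.ndarray:
        """Distinct observed event times, ascending."""
        return np.unique(self.Z[self.delta == 1])

    def subset(self, mask: np.ndarray) -> "BaselineCohort":
        return BaselineCohort(
            self.subject_id[mask], self.Z[mask], self.delta[mask], self.X[mask], self.time_unit
        )

    def resample(self, idx: np.ndarray) -> "BaselineCohort":
        """Subject resample (ids relabelled to stay unique)."""
        labels = np.array([f"b{k}" for k in range(len(idx))], dtype=object)
        return BaselineCohort(labels, self.Z[idx], self.delta[idx], self.X[idx], self.time_unit)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"id": self.subject_id, "time": self.Z, "event": self.delta, "marker": self.X}
        )


@dataclass(frozen=True)
class LongitudinalCohort:
    """Per-subject marker trajectories plus (Z, delta).

    ``visits`` is stored long-form: ``visit_subject`` indexes into the
    per-subject arrays; within each subject visit times are strictly
    increasing and never exceed that subject's observed time.
    """

    subject_id: np.ndarray
    Z: np.ndarray
    delta: np.ndarray
    visit_subject: np.ndarray = field(repr=False)  # int index into subject arrays
    visit_time: np.ndarray = field(repr=False)
    visit_value: np.ndarray = field(repr=False)
    time_unit: str = "days"

    def __post_init__(self):
        object.__setattr__(self, "subject_id", np.asarray(self.subject_id, dtype=object))
        object.__setattr__(self, "Z", np.asarray(self.Z, dtype=float))
        object.__setattr__(self, "delta", np.asarray(self.delta, dtype=int))
        object.__setattr__(self, "visit_subject", np.asarray(self.visit_subject, dtype=int))
        object.__setattr__(self, "visit_time", np.asarray(self.visit_time, dtype=float))
        object.__setattr__(self, "visit_value", np.asarray(self.visit_value, dtype=float))
        n = len(self.Z)
        if len(set(self.subject_id.tolist())) != n:
            raise CohortValidationError("subject ids must be unique")
        if np.any(self.Z <= 0) or not np.all(np.isfinite(self.Z)):
            raise CohortValidationError("all observed times must be finite and > 0")
        if not np.isin(self.delta, (0, 1)).all():
            raise CohortValidationError("event indicator must be 0 or 1")
        counts = np.bincount(self.visit_subject, minlength=n)
        if (counts == 0).any():
            missing = np.flatnonzero(counts == 0).tolist()
            raise CohortValidationError(f"every subject needs >= 1 visit; none for {missing}")
        for i in range(n):
            s = self.visit_time[self.visit_subject == i]
            if np.any(np.diff(s) <= 0):
                raise CohortValidationError(
                    f"visit times must be strictly increasing within subject {self.subject_id[i]!r}"
                )
            if np.any(s > self.Z[i]):
                raise CohortValidationError(
                    f"visit after observed time for subject {self.subject_id[i]!r}"
                )

    @property
    def n(self) -> int:
        return len(self.Z)

    def n_visits(self, i: int) -> int:
        return int((self.visit_subject == i).sum())

    def visits_of(self, i: int) -> tuple[np.ndarray, np.ndarray]:
        m = self.visit_subject == i
        return self.visit_time[m], self.visit_value[m]

    def resample(self, idx: np.ndarray) -> "LongitudinalCohort":
        """Whole-subject resample with relabelled ids."""
        vs, vt, vv = [], [], []
        for new_i, old_i in enumerate(idx):
            m = self.visit_subject == old_i
            vs.append(np.full(m.sum(), new_i))
            vt.append(self.visit_time[m])
            vv.append(self.visit_value[m])
        labels = np.array([f"b{k}" for k in range(len(idx))], dtype=object)
        return LongitudinalCohort(
            labels, self.Z[idx], self.delta[idx],
            np.concatenate(vs), np.concatenate(vt), np.concatenate(vv), self.time_unit,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": self.subject_id[self.visit_subject],
                "visit_time": self.visit_time,
                "marker": self.visit_value,
                "time": self.Z[self.visit_subject],
                "event": self.delta[self.visit_subject],
            }
        )


def _sep_for(path) -> str:
    return "\t" if str(path).endswith((".tsv", ".tab")) else ","


def _require_columns(df: pd.DataFrame, colmap: dict, path) -> None:
    missing = [v for v in colmap.values() if v not in df.columns]
    if missing:
        raise KeyError(f"{path}: missing column(s) {missing}; found {list(df.columns)}")


def read_baseline(path, column_map: dict | None = None, time_unit: str = "days") -> BaselineCohort:
    """Read a baseline cohort from a delimited file (CSV/TSV by extension).

    Rows with a missing time or marker are rejected and counted in the log;
    a non-{0,1} event value raises naming the offending row.
    """
    colmap = {**BASELINE_COLUMNS, **(column_map or {})}
    df = pd.read_csv(path, sep=_sep_for(path), float_precision="round_trip")
    _require_columns(df, colmap, path)
    sub = df[[colmap["id"], colmap["time"], colmap["event"], colmap["marker"]]].copy()
    sub.columns = ["id", "time", "event", "marker"]
    keep = sub[["time", "marker", "event"]].notna().all(axis=1)
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.warning("read_baseline: rejected %d row(s) with missing values", n_dropped)
    sub = sub[keep]
    bad = ~sub["event"].isin((0, 1))
    if bad.any():
        row = int(bad.idxmax())
        raise CohortValidationError(
            f"{path}: event value {sub.loc[row, 'event']!r} not in {{0,1}} at row {row}"
        )
    return BaselineCohort(
        sub["id"].to_numpy(object),
        sub["time"].to_numpy(float),
        sub["event"].to_numpy(int),
        sub["marker"].to_numpy(float),
        time_unit,
    )


def write_baseline(cohort: BaselineCohort, path) -> None:
    cohort.to_frame().to_csv(path, sep=_sep_for(path), index=False)


def read_longitudinal(
    path, column_map: dict | None = None, visit_policy: str = "drop-after-Z",
    time_unit: str = "days",
) -> LongitudinalCohort:
    """Read a long-format longitudinal cohort (one visit per row).

    ``visit_policy`` governs visits recorded after the subject's observed
    time: ``"drop-after-Z"`` removes them (count logged), ``"error"`` raises.
    """
    if visit_policy not in ("drop-after-Z", "error"):
        raise ValueError(f"unknown visit_policy {visit_policy!r}")
    colmap = {**LONGITUDINAL_COLUMNS, **(column_map or {})}
    df = pd.read_csv(path, sep=_sep_for(path), float_precision="round_trip")
    _require_columns(df, colmap, path)
    sub = df[[colmap[k] for k in ("id", "visit_time", "marker", "time", "event")]].copy()
    sub.columns = ["id", "visit_time", "marker", "time", "event"]
    keep = sub[["visit_time", "marker", "time", "event"]].notna().all(axis=1)
    if (~keep).any():
        logger.warning("read_longitudinal: rejected %d row(s) with missing values",
                       int((~keep).sum()))
        sub = sub[keep]
    if sub.duplicated(subset=["id", "visit_time"]).any():
        dup = sub[sub.duplicated(subset=["id", "visit_time"])].iloc[0]
        raise CohortValidationError(
            f"duplicate visit time {dup['visit_time']} for subject {dup['id']!r}"
        )
    late = sub["visit_time"] > sub["time"]
    if late.any():
        if visit_policy == "error":
            row = int(late.idxmax())
            raise CohortValidationError(
                f"{path}: visit after observed time at row {row} (policy=error)"
            )
        logger.warning("read_longitudinal: dropped %d visit(s) after observed time",
                       int(late.sum()))
        sub = sub[~late]
    sub = sub.sort_values(["id", "visit_time"], kind="mergesort")
    ids, inverse = np.unique(sub["id"].to_numpy(object), return_inverse=True)
    Z = np.empty(len(ids))
    delta = np.empty(len(ids), dtype=int)
    for i in range(len(ids)):
        rows = sub[inverse == i]
        Z[i] = rows["time"].iloc[0]
        delta[i] = int(rows["event"].iloc[0])
    return LongitudinalCohort(
        ids, Z, delta, inverse,
        sub["visit_time"].to_numpy(float), sub["marker"].to_numpy(float), time_unit,
    )


def write_longitudinal(lc: LongitudinalCohort, path) -> None:
    lc.to_frame().to_csv(path, sep=_sep_for(path), index=False)


def last_value_cohort(lc: LongitudinalCohort, landmark: float) -> BaselineCohort:
    """Landmark ("last value") reduction of a longitudinal cohort.

    Keeps exactly the subjects still at risk strictly beyond the landmark
    (``Z > s0``) that have at least one visit at or before it, and uses the
    marker value from the latest such visit. The time axis is unchanged
    (original scale). Idempotent under repeated application at the same
    landmark.
    """
    if landmark <= 0:
        raise ValueError("landmark must be > 0")
    ids, Z, delta, X = [], [], [], []
    for i in range(lc.n):
        if lc.Z[i] <= landmark:
            continue
        s, y = lc.visits_of(i)
        m = s <= landmark
        if not m.any():
            continue
        ids.append(lc.subject_id[i])
        Z.append(lc.Z[i])
        delta.append(lc.delta[i])
        X.append(y[m][-1])
    if not ids:
        raise CohortValidationError(f"no subject at risk with a visit at or before {landmark}")
    if len(ids) < 2:
        raise CohortValidationError("fewer than 2 subjects qualify at this landmark")
    return BaselineCohort(np.array(ids, object), Z, delta, X, lc.time_unit)
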