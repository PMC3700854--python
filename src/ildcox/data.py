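"""Core domain types and I/O for illness-death event histories.

Two tabular layouts move through the package:

* the **subject table** — one row per subject with entry time, time of the
  intermediate event ``d`` (if any), time of distant disease (if recorded),
  terminal time, terminal status and time-fixed covariates;
* the **interval table** — the start-stop counting-process layout, one row
  per at-risk interval per transition, with covariates evaluated at the
  interval's right endpoint.

Times are in years throughout.  A missing intermediate event is a true
missing value (NaN in the frame), never a sentinel time.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CENSORED",
    "EVENT",
    "SubjectRecord",
    "SubjectTable",
    "TransitionModelSpec",
    "SubjectTableError",
    "read_subjects",
    "write_subjects",
    "read_intervals",
    "write_intervals",
    "validate_intervals",
]

#: integer status codes used internally
CENSORED = 0
EVENT = 1

#: canonical subject-table columns, in order, before covariates
SUBJECT_COLUMNS = ["id", "entry", "d", "dd_time", "time", "status"]

#: canonical interval-table columns before covariates
INTERVAL_COLUMNS = ["id", "transition", "start", "stop", "status"]

#: recognised transition labels in the interval table
TRANSITIONS = ("12", "13", "23", "J")

DEFAULT_STATUS_CODES: Mapping[object, int] = {0: CENSORED, 1: EVENT}


class SubjectTableError(ValueError):
    """Raised when a subject or interval table violates its invariants."""


@dataclasses.dataclass(frozen=True)
class SubjectRecord:
    """One subject's event history.

    Attributes
    ----------
    subject_id : opaque identifier.
    entry_time : delayed-entry time in years (0 for cohorts followed from
        diagnosis).
    d : time of the intermediate event in years since diagnosis, or None.
    dd_time : time of distant disease, or None; consumed only by the
        endpoint-convention and imputation rules.
    terminal_time : exit time in years.
    terminal_status : ``EVENT`` (absorbing event observed) or ``CENSORED``.
    z : mapping of time-fixed covariate name -> value.
    """

    subject_id: object
    entry_time: float
    d: float | None
    dd_time: float | None
    terminal_time: float
    terminal_status: int
    z: Mapping[str, float]

    def __post_init__(self) -> None:
        if self.terminal_time < self.entry_time:
            raise SubjectTableError(
                f"subject {self.subject_id}: terminal time {self.terminal_time} "
                f"precedes entry {self.entry_time}"
            )
        if self.d is not None and not (self.entry_time <= self.d <= self.terminal_time):
            raise SubjectTableError(
                f"subject {self.subject_id}: intermediate-event time {self.d} outside "
                f"({self.entry_time}, {self.terminal_time}]"
            )
        if self.terminal_status not in (CENSORED, EVENT):
            raise SubjectTableError(
                f"subject {self.subject_id}: unknown status {self.terminal_status!r}"
            )


class SubjectTable:
    """A cohort of subjects backed by a pandas DataFrame.

    The frame carries the columns of :data:`SUBJECT_COLUMNS` followed by the
    covariate columns; ``d`` and ``dd_time`` use NaN for "absent".
    """

    def __init__(self, df: pd.DataFrame, covariates: Sequence[str] | None = None):
        missing = [c for c in SUBJECT_COLUMNS if c not in df.columns]
        if missing:
            raise SubjectTableError(f"subject table missing columns {missing}")
        if covariates is None:
            covariates = [c for c in df.columns if c not in SUBJECT_COLUMNS]
        self.covariates = list(covariates)
        cols = SUBJECT_COLUMNS + self.covariates
        self.df = df.loc[:, cols].reset_index(drop=True).copy()
        for c in ("entry", "d", "dd_time", "time"):
            self.df[c] = pd.to_numeric(self.df[c])
        self.df["status"] = self.df["status"].astype(int)
        self._validate()

    # -- construction -------------------------------------------------
    @classmethod
    def from_records(cls, records: Iterable[SubjectRecord]) -> "SubjectTable":
        rows = []
        for r in records:
            row = {
                "id": r.subject_id,
                "entry": r.entry_time,
                "d": np.nan if r.d is None else r.d,
                "dd_time": np.nan if r.dd_time is None else r.dd_time,
                "time": r.terminal_time,
                "status": r.terminal_status,
            }
            row.update(r.z)
            rows.append(row)
        return cls(pd.DataFrame(rows))

    def _validate(self) -> None:
        df = self.df
        bad = df.index[df["time"] < df["entry"]]
        if len(bad):
            ids = df.loc[bad, "id"].tolist()
            raise SubjectTableError(f"terminal time precedes entry for subjects {ids}")
        has_d = df["d"].notna()
        bad = df.index[has_d & ((df["d"] < df["entry"]) | (df["d"] > df["time"]))]
        if len(bad):
            ids = df.loc[bad, "id"].tolist()
            raise SubjectTableError(
                f"intermediate-event time outside (entry, terminal] for subjects {ids}"
            )
        if not df["status"].isin([CENSORED, EVENT]).all():
            bad = df.loc[~df["status"].isin([CENSORED, EVENT]), "id"].tolist()
            raise SubjectTableError(f"unknown status codes for subjects {bad}")
        if df["id"].duplicated().any():
            dup = df.loc[df["id"].duplicated(), "id"].tolist()
            raise SubjectTableError(f"duplicate subject ids {dup}")

    # -- access -------------------------------------------------------
    def __len__(self) -> int:
        return len(self.df)

    def __iter__(self) -> Iterator[SubjectRecord]:
        for _, r in self.df.iterrows():
            yield SubjectRecord(
                subject_id=r["id"],
                entry_time=float(r["entry"]),
                d=None if pd.isna(r["d"]) else float(r["d"]),
                dd_time=None if pd.isna(r["dd_time"]) else float(r["dd_time"]),
                terminal_time=float(r["time"]),
                terminal_status=int(r["status"]),
                z={c: r[c] for c in self.covariates},
            )

    def copy(self) -> "SubjectTable":
        return SubjectTable(self.df.copy(), self.covariates)

    def equals(self, other: "SubjectTable") -> bool:
        return self.covariates == other.covariates and self.df.equals(other.df)


@dataclasses.dataclass
class TransitionModelSpec:
    """Declarative description of one transition model.

    ``approach`` is "J" (joint 1->3 / 2->3 hazard with a state indicator)
    or "S" (separate per-transition fits).  ``clock`` selects the 2->3 time
    scale for approach S; ``relation`` names the joint-hazard relation
    (J.I ... J.IV, J.FP).  ``f_terms`` lists the sojourn/waiting-time term
    descriptors (see :mod:`ildcox.restructure`).
    """

    approach: str
    endpoint: str = "overall_survival"
    clock: str | None = None
    relation: str | None = None
    f_terms: Sequence = ()
    fixed_covariates: Sequence[str] = ()

    def __post_init__(self) -> None:
        if self.approach not in ("J", "S"):
            raise ValueError(f"unknown approach {self.approach!r}")
        if self.endpoint not in ("overall_survival", "distant_disease_free"):
            raise ValueError(f"unknown endpoint {self.endpoint!r}")
        if self.approach == "J":
            if self.clock is not None:
                raise ValueError("clock applies to approach S only")
            if self.relation is None:
                raise ValueError("approach J requires a relation label")
            if self.relation == "J.I" and len(self.f_terms):
                raise ValueError("relation J.I carries no time-varying terms")
        else:
            if self.relation is not None:
                raise ValueError("relation applies to approach J only")
            if self.clock not in (None, "forward", "reset"):
                raise ValueError(f"unknown clock {self.clock!r}")


# ---------------------------------------------------------------------------
# subject-table I/O


def read_subjects(
    path,
    schema: Mapping[str, str] | None = None,
    status_codes: Mapping[object, int] | None = None,
    covariates: Sequence[str] | None = None,
    sep: str = ",",
) -> SubjectTable:
    """Read a subject table from delimited text.

    Parameters
    ----------
    schema : optional mapping from canonical names (``id``, ``entry``, ``d``,
        ``dd_time``, ``time``, ``status``) to the file's column names.
        Unmapped canonical names default to themselves; ``entry``, ``d`` and
        ``dd_time`` may be absent from the file (entry defaults to 0, the
        other two to missing).
    status_codes : mapping from raw status values to {0: censored,
        1: absorbing event}; defaults to the identity on {0, 1}.
    covariates : covariate columns; default, every unclaimed column.
    """
    raw = pd.read_csv(path, sep=sep)
    schema = dict(schema or {})
    colmap = {k: schema.get(k, k) for k in SUBJECT_COLUMNS}
    status_codes = dict(status_codes or DEFAULT_STATUS_CODES)

    df = pd.DataFrame()
    if colmap["id"] not in raw.columns:
        raise SubjectTableError(f"missing id column {colmap['id']!r}")
    df["id"] = raw[colmap["id"]]
    df["entry"] = pd.to_numeric(raw[colmap["entry"]]) if colmap["entry"] in raw.columns else 0.0
    for key in ("d", "dd_time"):
        df[key] = pd.to_numeric(raw[colmap[key]]) if colmap[key] in raw.columns else np.nan
    for key in ("time",):
        if colmap[key] not in raw.columns:
            raise SubjectTableError(f"missing column {colmap[key]!r}")
        df[key] = pd.to_numeric(raw[colmap[key]])
    if colmap["status"] not in raw.columns:
        raise SubjectTableError(f"missing column {colmap['status']!r}")

    raw_status = raw[colmap["status"]]
    decoded = raw_status.map(status_codes)
    if decoded.isna().any():
        bad = raw.loc[decoded.isna(), colmap["id"]].tolist()
        raise SubjectTableError(
            f"unknown status codes {sorted(set(raw_status[decoded.isna()]))} "
            f"for subjects {bad}"
        )
    df["status"] = decoded.astype(int)

    claimed = {colmap[k] for k in SUBJECT_COLUMNS}
    if covariates is None:
        covariates = [c for c in raw.columns if c not in claimed]
    for c in covariates:
        df[c] = raw[c]
    neg = df.index[(df[["entry", "time"]] < 0).any(axis=1)]
    if len(neg):
        raise SubjectTableError(f"negative times for subjects {df.loc[neg, 'id'].tolist()}")
    return SubjectTable(df, covariates)


def write_subjects(table: SubjectTable, path) -> None:
    table.df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# interval-table I/O


def validate_intervals(df: pd.DataFrame) -> None:
    """Check the counting-process invariants of an interval table.

    Within one subject and one transition the half-open intervals
    (start, stop] must be strictly increasing, disjoint, and carry at most
    one event.
    """
    missing = [c for c in INTERVAL_COLUMNS if c not in df.columns]
    if missing:
        raise SubjectTableError(f"interval table missing columns {missing}")
    if not df["transition"].astype(str).isin(TRANSITIONS).all():
        bad = sorted(set(df["transition"].astype(str)) - set(TRANSITIONS))
        raise SubjectTableError(f"unknown transition labels {bad}")
    if (df["stop"] <= df["start"]).any():
        bad = df.loc[df["stop"] <= df["start"], "id"].tolist()
        raise SubjectTableError(f"degenerate intervals (stop <= start) for subjects {bad}")
    if not df["status"].isin([0, 1]).all():
        raise SubjectTableError("interval status must be 0/1")
    for (sid, trans), g in df.groupby(["id", "transition"], sort=False):
        start = g["start"].to_numpy()
        stop = g["stop"].to_numpy()
        order = np.argsort(start, kind="stable")
        if np.any(start[order][1:] < stop[order][:-1]):
            raise SubjectTableError(
                f"overlapping intervals for subject {sid}, transition {trans}"
            )
        if int(g["status"].sum()) > 1:
            raise SubjectTableError(
                f"multiple events for subject {sid}, transition {trans}"
            )


def write_intervals(df: pd.DataFrame, path) -> None:
    """Write an interval table as CSV at full float precision.

    Floats are written with Python's shortest round-trip repr, so
    ``read_intervals(write_intervals(df))`` reproduces the frame exactly.
    """
    validate_intervals(df)
    df.to_csv(path, index=False)


def read_intervals(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if len(df):
        validate_intervals(df)
    else:
        missing = [c for c in INTERVAL_COLUMNS if c not in df.columns]
        if missing:
            raise SubjectTableError(f"interval table missing columns {missing}")
    df["transition"] = df["transition"].astype(str)
    return df
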