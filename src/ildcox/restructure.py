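"""Counting-process restructuring of illness-death event histories.

Subjects are turned into start-stop at-risk intervals for either

* the **joint** layout: transitions 1->3 and 2->3 share one hazard whose
  design carries a time-varying state indicator and sojourn/waiting-time
  terms f(d, t - d); transition 1->2 is laid out separately; or
* the **separate** layout: one start-stop table per transition, with the
  2->3 table left-truncated at the intermediate-event time d on the
  "clock forward" scale (time since diagnosis), or shifted to the
  "clock reset" scale (time since the intermediate event).

Intervals are half-open (start, stop]: a subject is at risk at u iff
start < u <= stop.  Continuously time-varying terms (exp(-(t-d)), FP
bases of t - d) are evaluated at each interval's stop, with intervals cut
at every observed event time inside the affected window so the partial
likelihood sees the exact covariate value at each event time; rows on
which every term is step-constant are left uncut (the partial likelihood
is invariant to refining them).
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Sequence

import numpy as np
import pandas as pd

from .data import CENSORED, EVENT, SubjectTable, SubjectTableError
from .fracpoly import FPTransform, fp_design_columns

__all__ = [
    "FTerm",
    "INDICATOR",
    "D_LINEAR",
    "EXP_NEG_SOJOURN",
    "fp_term",
    "impute_event_times",
    "apply_endpoint_convention",
    "to_joint_layout",
    "to_separate_layout",
    "term_columns",
]

MONTH = 1.0 / 12.0


@dataclasses.dataclass(frozen=True)
class FTerm:
    """One term of the sojourn-time-dependent covariate function f(d, t-d).

    kinds:
      ``indicator``        1{t >= d}, the state-2 membership indicator;
      ``d_linear``         the waiting time d, gated by the indicator;
      ``exp_neg_sojourn``  exp(-(t - d)), gated;
      ``fp``               a fractional-polynomial basis of the sojourn
                           time t - d or of d (``variable``), gated.
    """

    kind: str
    transform: FPTransform | None = None
    variable: str = "sojourn"

    def __post_init__(self):
        if self.kind not in ("indicator", "d_linear", "exp_neg_sojourn", "fp"):
            raise ValueError(f"unknown f-term kind {self.kind!r}")
        if (self.kind == "fp") != (self.transform is not None):
            raise ValueError("fp terms require a transform; others must not carry one")

    @property
    def continuous(self) -> bool:
        """True if the term varies continuously with t inside state 2."""
        return self.kind == "exp_neg_sojourn" or (
            self.kind == "fp" and self.variable == "sojourn"
        )

    def columns(self) -> list[str]:
        if self.kind == "indicator":
            return ["in_state_2"]
        if self.kind == "d_linear":
            return ["onset_time"]
        if self.kind == "exp_neg_sojourn":
            return ["exp_neg_sojourn"]
        return self.transform.labels(self.variable)


INDICATOR = FTerm("indicator")
D_LINEAR = FTerm("d_linear")
EXP_NEG_SOJOURN = FTerm("exp_neg_sojourn")


def fp_term(powers, variable: str = "sojourn") -> FTerm:
    return FTerm("fp", FPTransform(tuple(np.atleast_1d(powers))), variable)


def term_columns(f_terms: Sequence[FTerm]) -> list[str]:
    cols: list[str] = []
    for t in f_terms:
        cols.extend(t.columns())
    return cols


# ---------------------------------------------------------------------------
# data-preparation conventions


def impute_event_times(subjects: SubjectTable, rng_seed: int | None = None) -> SubjectTable:
    """Resolve intermediate-event times that coincide with other events.

    * intermediate event detected exactly at death: moved one month earlier;
    * intermediate event recorded simultaneously with distant disease:
      redrawn uniformly on the three months before the distant-disease
      time (reproducible under ``rng_seed``).

    Subjects without such coincidences are returned unchanged.
    """
    rng = np.random.default_rng(rng_seed)
    df = subjects.df.copy()
    d = df["d"].to_numpy(dtype=float)
    dd = df["dd_time"].to_numpy(dtype=float)
    time = df["time"].to_numpy(dtype=float)
    entry = df["entry"].to_numpy(dtype=float)
    status = df["status"].to_numpy()

    has_d = ~np.isnan(d)
    with np.errstate(invalid="ignore"):
        simultaneous = has_d & ~np.isnan(dd) & (d == dd)
        at_death = has_d & (status == EVENT) & (d == time) & ~simultaneous

    new_d = d.copy()
    new_d[at_death] = time[at_death] - MONTH
    idx = np.flatnonzero(simultaneous)
    for i in idx:
        new_d[i] = rng.uniform(dd[i] - 3 * MONTH, dd[i])
    bad = np.flatnonzero((at_death | simultaneous) & (new_d < entry))
    if len(bad):
        ids = df.loc[bad, "id"].tolist()
        raise SubjectTableError(
            f"imputation would move the intermediate event before entry for subjects {ids}"
        )
    df["d"] = new_d
    return SubjectTable(df, subjects.covariates)


def apply_endpoint_convention(subjects: SubjectTable, endpoint: str) -> SubjectTable:
    """Apply the endpoint's censoring convention to the subject table.

    ``overall_survival``: subjects with distant disease but no intermediate
    event are censored at the distant-disease time (they leave the
    illness-death scheme at that point).  ``distant_disease_free``: the
    terminal event is the earlier of distant disease and death.
    """
    if endpoint not in ("overall_survival", "distant_disease_free"):
        raise ValueError(f"unknown endpoint {endpoint!r}")
    df = subjects.df.copy()
    d = df["d"].to_numpy(dtype=float)
    dd = df["dd_time"].to_numpy(dtype=float)
    has_d = ~np.isnan(d)
    has_dd = ~np.isnan(dd)
    if endpoint == "overall_survival":
        sel = has_dd & ~has_d
        df.loc[sel, "time"] = dd[sel]
        df.loc[sel, "status"] = CENSORED
    else:
        conflict = has_d & has_dd & (d > dd)
        if conflict.any():
            ids = df.loc[conflict, "id"].tolist()
            raise SubjectTableError(
                f"intermediate event after distant disease for subjects {ids}"
            )
        sel = has_dd & (dd <= df["time"].to_numpy(dtype=float))
        df.loc[sel, "time"] = dd[sel]
        df.loc[sel, "status"] = EVENT
    return SubjectTable(df, subjects.covariates)


# ---------------------------------------------------------------------------
# layout construction


def _evaluate_terms(
    df: pd.DataFrame, f_terms: Sequence[FTerm]
) -> tuple[pd.DataFrame, list[str]]:
    """Append the f-term columns (gated to 0 before the event) to a layout."""
    cols: list[str] = []
    for t in f_terms:
        if t.kind == "indicator":
            cols.append("in_state_2")
        elif t.kind == "d_linear":
            df["onset_time"] = df["in_state_2"] * df["_onset"].fillna(0.0)
            cols.append("onset_time")
        elif t.kind == "exp_neg_sojourn":
            s = df["stop"] - df["_d"]
            df["exp_neg_sojourn"] = np.where(df["in_state_2"] > 0, np.exp(-s), 0.0)
            cols.append("exp_neg_sojourn")
        else:
            df, names = fp_design_columns(df, t.transform, t.variable)
            cols.extend(names)
    return df, cols


def _subject_pieces(entry, exit_, d, cuts, minimal):
    """Breakpoints (ascending stops) of one subject's at-risk time."""
    pts = [exit_]
    if d is not None and entry < d < exit_:
        pts.append(d)
    if cuts is not None and len(cuts):
        if minimal:
            if d is not None:
                lo = np.searchsorted(cuts, max(d, entry), side="right")
            else:
                lo = len(cuts)
        else:
            lo = np.searchsorted(cuts, entry, side="right")
        hi = np.searchsorted(cuts, exit_, side="left")
        if hi > lo:
            pts.extend(cuts[lo:hi])
    stops = np.unique(np.asarray(pts, dtype=float))
    starts = np.concatenate(([entry], stops[:-1]))
    return starts, stops


def _layout_frame(rows, covariates):
    if not rows:
        return pd.DataFrame(
            columns=["id", "transition", "start", "stop", "status", *covariates]
        )
    df = pd.DataFrame(rows)
    for c in covariates:
        df[c] = df[c].astype(float) if df[c].dtype == object else df[c]
    return df


def to_joint_layout(
    subjects: SubjectTable,
    f_terms: Sequence[FTerm] = (INDICATOR,),
    split_times: Sequence[float] | None = None,
    drop_simultaneous: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Build the joint (1 u 2) -> 3 layout plus the 1 -> 2 layout.

    Returns ``(joint, trans12)`` interval frames.  The joint frame carries
    the f-term columns (gated to exactly 0 before d), the time-fixed
    covariates, and meta columns ``_d``/``_onset`` (the intermediate-event
    time on the layout's clock / in absolute terms) used by FP machinery.

    ``split_times`` defaults to the observed terminal-event times when any
    f-term varies continuously inside state 2 (only the post-d rows of ill
    subjects are cut — the partial likelihood is unchanged by refining
    step-constant rows); pass an explicit grid to cut every subject at
    every time. ``drop_simultaneous`` drops subjects whose intermediate
    event coincides with their exit instead of keeping them with zero
    post-event exposure.
    """
    f_terms = list(f_terms)
    df = subjects.df
    needs_split = any(t.continuous for t in f_terms)
    minimal = split_times is None
    if split_times is None:
        split_times = (
            np.unique(df.loc[df["status"] == EVENT, "time"].to_numpy(dtype=float))
            if needs_split
            else np.empty(0)
        )
    cuts = np.unique(np.asarray(split_times, dtype=float))

    zcols = subjects.covariates
    keep = np.ones(len(df), dtype=bool)
    starts_parts, stops_parts, counts = [], [], []
    t12_rows = []
    d_all = df["d"].to_numpy(dtype=float)
    for i, row in enumerate(df.itertuples(index=False)):
        entry, exit_, status = float(row.entry), float(row.time), int(row.status)
        d = None if np.isnan(d_all[i]) else d_all[i]
        if d is not None and d == exit_ and drop_simultaneous:
            keep[i] = False
            continue
        starts, stops = _subject_pieces(entry, exit_, d, cuts, minimal)
        starts_parts.append(starts)
        stops_parts.append(stops)
        counts.append(len(stops))
        # transition 1 -> 2: at risk until min(d, exit)
        t12_stop = exit_ if d is None else d
        if t12_stop > entry:
            rec = {
                "id": row.id,
                "transition": "12",
                "start": entry,
                "stop": t12_stop,
                "status": 1 if d is not None else 0,
            }
            rec.update({c: getattr(row, c) for c in zcols})
            t12_rows.append(rec)
        elif d is not None:
            warnings.warn(
                f"subject {row.id}: intermediate event at entry; no 1->2 exposure",
                RuntimeWarning,
            )
    kept = df.loc[keep]
    counts = np.asarray(counts, dtype=int)
    start = np.concatenate(starts_parts) if starts_parts else np.empty(0)
    stop = np.concatenate(stops_parts) if stops_parts else np.empty(0)
    d_rep = np.repeat(kept["d"].to_numpy(dtype=float), counts)
    status_col = np.zeros(len(start), dtype=int)
    last = np.cumsum(counts) - 1
    status_col[last] = kept["status"].to_numpy(dtype=int)
    joint = pd.DataFrame(
        {
            "id": np.repeat(kept["id"].to_numpy(), counts),
            "transition": "J",
            "start": start,
            "stop": stop,
            "status": status_col,
            "in_state_2": np.where(~np.isnan(d_rep) & (start >= d_rep), 1.0, 0.0),
            "_d": d_rep,
            "_onset": d_rep,
        }
    )
    for c in zcols:
        joint[c] = np.repeat(kept[c].to_numpy(), counts)
    joint, _ = _evaluate_terms(joint, f_terms)
    t12 = _layout_frame(t12_rows, zcols)
    return joint, t12


def to_separate_layout(
    subjects: SubjectTable,
    transition: str,
    clock: str = "forward",
    f_terms: Sequence[FTerm] = (),
    split_times: Sequence[float] | None = None,
    drop_simultaneous: bool = False,
) -> pd.DataFrame:
    """Start-stop layout for one transition of the separate approach.

    * ``"12"``: at risk on (entry, min(d, exit)]; event iff d observed.
    * ``"13"``: same risk window; event iff the absorbing event occurs
      without an intermediate event.
    * ``"23"``: only subjects with d; ``clock="forward"`` keeps the time
      since diagnosis with left truncation at d, ``clock="reset"`` uses the
      time since the intermediate event.  The waiting time d is available
      as the fixed covariate ``onset_time``; sojourn terms from ``f_terms``
      are evaluated at interval stops.
    """
    if transition not in ("12", "13", "23"):
        raise ValueError(f"unknown transition {transition!r}")
    if clock not in ("forward", "reset"):
        raise ValueError(f"unknown clock {clock!r}")
    if clock == "reset" and transition != "23":
        raise ValueError("clock reset applies to transition 2->3 only")
    f_terms = list(f_terms)
    if transition != "23" and f_terms:
        raise ValueError("sojourn terms apply to transition 2->3 only")

    df = subjects.df
    zcols = subjects.covariates
    rows = []

    if transition in ("12", "13"):
        for row in df.itertuples(index=False):
            entry, exit_ = float(row.entry), float(row.time)
            d = None if pd.isna(row.d) else float(row.d)
            stop = exit_ if d is None else d
            if stop <= entry:
                continue
            if transition == "12":
                status = 1 if d is not None else 0
            else:
                status = 1 if (d is None and int(row.status) == EVENT) else 0
            rec = {
                "id": row.id,
                "transition": transition,
                "start": entry,
                "stop": stop,
                "status": status,
            }
            rec.update({c: getattr(row, c) for c in zcols})
            rows.append(rec)
        return _layout_frame(rows, zcols)

    # transition 2 -> 3
    ill = df[df["d"].notna()]
    needs_split = any(t.continuous for t in f_terms)
    minimal = split_times is None
    if split_times is None:
        if needs_split:
            ev = ill[(ill["status"] == EVENT) & (ill["time"] > ill["d"])]
            times = ev["time"].to_numpy(dtype=float)
            if clock == "reset":
                times = times - ev["d"].to_numpy(dtype=float)
            split_times = np.unique(times)
        else:
            split_times = np.empty(0)
    cuts = np.unique(np.asarray(split_times, dtype=float))

    for row in ill.itertuples(index=False):
        d, exit_, status = float(row.d), float(row.time), int(row.status)
        if exit_ <= d:
            if not drop_simultaneous and exit_ == d:
                continue  # zero post-event exposure; nothing to contribute
            continue
        if clock == "forward":
            origin, stop_final, clock_d = d, exit_, d
        else:
            origin, stop_final, clock_d = 0.0, exit_ - d, 0.0
        starts, stops = _subject_pieces(origin, stop_final, None, cuts, False)
        z = {c: getattr(row, c) for c in zcols}
        for j, (a, b) in enumerate(zip(starts, stops)):
            rec = {
                "id": row.id,
                "transition": "23",
                "start": a,
                "stop": b,
                "status": status if j == len(stops) - 1 else 0,
                "in_state_2": 1.0,
                "_d": clock_d,
                "_onset": d,
            }
            rec.update(z)
            rows.append(rec)
    out = _layout_frame(rows, zcols)
    if len(out) == 0:
        return out
    out, _ = _evaluate_terms(out, f_terms)
    return out
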