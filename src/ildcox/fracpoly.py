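"""Fractional polynomials for time-varying covariates.

A fractional polynomial (FP) of a positive variable X is a linear
combination of power transforms X^p with powers drawn from the conventional
set S = {-2, -1, -0.5, 0, 0.5, 1, 2, 3}, where X^0 denotes log(X).  A
one-term FP (FP1) has a single power; a two-term FP (FP2) has an unordered
pair of powers, and a repeated power (p, p) uses the basis
(X^p, X^p * log X).  That yields 8 FP1 and C(8,2) + 8 = 36 FP2 candidates.

Here the FPs are applied to the *time-varying* covariates of the 2->3
transition of an illness-death model — the sojourn time t - d or the
waiting time d — so the basis columns are evaluated on counting-process
intervals and gated to zero before the intermediate event.  Candidates are
compared by AIC of the resulting Cox fits.
"""

from __future__ import annotations

import dataclasses
import itertools
import json
import math
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from . import coxtv

__all__ = [
    "FP_POWERS",
    "FP_EPS",
    "FPTransform",
    "FPCandidate",
    "FPSelectionReport",
    "enumerate_fp1",
    "enumerate_fp2",
    "fp_design_columns",
    "select_fp",
    "select_fp_multi",
]

#: the conventional power set S
FP_POWERS = (-2.0, -1.0, -0.5, 0.0, 0.5, 1.0, 2.0, 3.0)

#: origin shift used inside log and negative/zero powers (one day, in years)
#: to stabilise near-zero sojourn times
FP_EPS = 1.0 / 365.0

#: variables an FP may act on: sojourn time t - d or waiting time d
FP_VARIABLES = ("sojourn", "onset")


def _power_label(p: float) -> str:
    s = f"{p:g}"
    return s.replace("-", "m").replace(".", "_")


@dataclasses.dataclass(frozen=True)
class FPTransform:
    """A one- or two-term fractional polynomial.

    ``powers`` holds one or two elements of :data:`FP_POWERS`; two-term
    powers are stored sorted so (a, b) and (b, a) are the same candidate.
    """

    powers: tuple

    def __post_init__(self) -> None:
        p = tuple(float(x) for x in self.powers)
        if len(p) not in (1, 2):
            raise ValueError("an FP has one or two powers")
        if any(x not in FP_POWERS for x in p):
            raise ValueError(f"powers must come from {FP_POWERS}, got {p}")
        if len(p) == 2:
            p = tuple(sorted(p))
        object.__setattr__(self, "powers", p)

    @property
    def m(self) -> int:
        return len(self.powers)

    @property
    def repeated(self) -> bool:
        return self.m == 2 and self.powers[0] == self.powers[1]

    def basis(self, x: np.ndarray, eps: float = FP_EPS) -> np.ndarray:
        """Evaluate the basis columns at strictly positive ``x``.

        Returns an array of shape (len(x), m).  The origin shift ``eps`` is
        added inside log and non-positive powers; pure positive powers use
        x unshifted.
        """
        x = np.asarray(x, dtype=float)
        if np.any(x <= 0):
            raise ValueError("FP basis requires strictly positive arguments")
        shifted = x + eps

        def one(p: float) -> np.ndarray:
            if p == 0:
                return np.log(shifted)
            if p < 0:
                return shifted ** p
            return x ** p

        cols = [one(self.powers[0])]
        if self.m == 2:
            if self.repeated:
                cols.append(one(self.powers[0]) * np.log(shifted))
            else:
                cols.append(one(self.powers[1]))
        return np.column_stack(cols)

    def labels(self, variable: str) -> list[str]:
        base = [f"{variable}_p{_power_label(p)}" for p in self.powers]
        if self.repeated:
            base[1] = base[1] + "_log"
        return base

    def describe(self) -> str:
        if self.m == 1:
            return f"FP1({self.powers[0]:g})"
        return f"FP2({self.powers[0]:g}, {self.powers[1]:g})"


def enumerate_fp1() -> list[FPTransform]:
    """The 8 one-term candidates, in ascending power order."""
    return [FPTransform((p,)) for p in FP_POWERS]


def enumerate_fp2() -> list[FPTransform]:
    """The 36 two-term candidates: all unordered pairs including repeats."""
    out = [FPTransform((p, p)) for p in FP_POWERS]
    out += [FPTransform(pair) for pair in itertools.combinations(FP_POWERS, 2)]
    out.sort(key=lambda t: t.powers)
    return out


def fp_design_columns(
    intervals: pd.DataFrame,
    transform: FPTransform,
    variable: str = "sojourn",
    eps: float = FP_EPS,
) -> tuple[pd.DataFrame, list[str]]:
    """Append the FP basis columns of a time-varying covariate to a layout.

    ``variable`` is "sojourn" (t - d, evaluated at each interval's stop) or
    "onset" (the waiting time d).  Columns are evaluated only on intervals
    after the intermediate event (gating column ``in_state_2`` equal to 1)
    and are exactly 0 elsewhere.  Returns the augmented frame and the new
    column names.
    """
    if variable not in FP_VARIABLES:
        raise ValueError(f"variable must be one of {FP_VARIABLES}")
    meta = "_d" if variable == "sojourn" else "_onset"
    for required in ("in_state_2", meta):
        if required not in intervals.columns:
            raise ValueError(
                f"layout lacks {required!r}; build it with the joint/separate "
                "restructuring including the state indicator"
            )
    gate = intervals["in_state_2"].to_numpy(dtype=float)
    on = gate > 0
    if variable == "sojourn":
        x = intervals["stop"].to_numpy(dtype=float) - intervals[meta].to_numpy(dtype=float)
    else:
        x = intervals[meta].to_numpy(dtype=float)
    if np.any(on & ~(x > -eps)):
        bad = intervals.index[on & ~(x > -eps)][:5].tolist()
        raise ValueError(f"non-positive FP argument on post-event intervals {bad}")
    # clip exact zeros entering pure positive powers; eps handles the rest
    xx = np.where(on, np.maximum(x, eps * 1e-9), 1.0)
    cols = transform.basis(xx, eps=eps)
    cols[~on] = 0.0
    names = transform.labels(variable)
    out = intervals.copy()
    for j, name in enumerate(names):
        out[name] = cols[:, j]
    return out, names


# ---------------------------------------------------------------------------
# AIC-based selection


@dataclasses.dataclass
class FPCandidate:
    transform: FPTransform | None  # None => reference model without the term
    label: str
    fit: "coxtv.CoxFit | None"
    aic: float
    converged: bool


@dataclasses.dataclass
class FPSelectionReport:
    """Outcome of one AIC sweep over the FP candidate space.

    ``candidates`` holds every fitted FP model; ``aic_null`` and
    ``aic_linear`` are the reference AICs of the model omitting the term and
    of the straight-line model (identical to FP1 with p = 1).
    """

    variable: str
    candidates: list[FPCandidate]
    best: FPCandidate
    aic_null: float
    aic_linear: float
    n_failed: int = 0
    converged: bool = True

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "model": c.label,
                "m": 0 if c.transform is None else c.transform.m,
                "powers": "" if c.transform is None else str(c.transform.powers),
                "aic": c.aic,
                "converged": c.converged,
            }
            for c in self.candidates
        ]
        df = pd.DataFrame(rows).sort_values("aic").reset_index(drop=True)
        df["delta_aic"] = df["aic"] - self.best.aic
        return df

    def to_json(self) -> str:
        payload = {
            "variable": self.variable,
            "aic_null": self.aic_null,
            "aic_linear": self.aic_linear,
            "best": {
                "label": self.best.label,
                "powers": None if self.best.transform is None else self.best.transform.powers,
                "aic": self.best.aic,
            },
            "n_failed": self.n_failed,
            "candidates": [
                {
                    "label": c.label,
                    "powers": None if c.transform is None else c.transform.powers,
                    "aic": c.aic,
                    "converged": c.converged,
                }
                for c in self.candidates
            ],
        }
        return json.dumps(payload, indent=2)


def _fit_candidate(
    factory: Callable,
    transform: FPTransform | None,
    variable: str,
    **fit_kwargs,
) -> tuple["coxtv.CoxFit | None", float, bool]:
    intervals, covariate_cols = factory(transform)
    try:
        fit = coxtv.fit_cox(intervals, covariate_cols, **fit_kwargs)
    except coxtv.CoxError:
        return None, math.inf, False
    if not fit.converged:
        return fit, math.inf, False
    return fit, fit.aic, True


def make_layout_factory(
    layout: pd.DataFrame,
    base_columns: Sequence[str],
    variable: str = "sojourn",
    eps: float = FP_EPS,
) -> Callable:
    """Factory over a fixed counting-process layout.

    The splitting is done once; each candidate only appends its basis
    columns.  ``factory(None)`` returns the base model's design, so the
    null and straight-line references share the same rows.
    """

    def factory(transform: FPTransform | None):
        if transform is None:
            return layout, list(base_columns)
        aug, names = fp_design_columns(layout, transform, variable, eps=eps)
        return aug, list(base_columns) + names

    return factory


def select_fp(
    intervals_factory,
    variable: str = "sojourn",
    base_columns: Sequence[str] = (),
    include_fp2: bool = True,
    eps: float = FP_EPS,
    **fit_kwargs,
) -> FPSelectionReport:
    """Fit and rank the FP candidate space for one time-varying covariate.

    ``intervals_factory`` is either a counting-process layout DataFrame
    (already split at event times, with the ``in_state_2`` gate and ``_d``)
    or a callable ``factory(transform) -> (intervals, covariate_columns)``.
    Fits the null model (term omitted), the straight line, all 8 FP1 and —
    unless ``include_fp2=False`` — all 36 FP2 candidates, and returns the
    full AIC table with the arg-min.  Ties are broken toward fewer terms,
    then lexicographically smaller powers.
    """
    if callable(intervals_factory):
        factory = intervals_factory
    else:
        factory = make_layout_factory(intervals_factory, base_columns, variable, eps)

    null_fit, aic_null, _ = _fit_candidate(factory, None, variable, **fit_kwargs)

    candidates: list[FPCandidate] = []
    pool = enumerate_fp1() + (enumerate_fp2() if include_fp2 else [])
    n_failed = 0
    for tr in pool:
        fit, aic, ok = _fit_candidate(factory, tr, variable, **fit_kwargs)
        if not ok:
            n_failed += 1
        candidates.append(FPCandidate(tr, tr.describe(), fit, aic, ok))

    linear = next(c for c in candidates if c.transform == FPTransform((1.0,)))
    usable = [c for c in candidates if c.converged]
    if not usable:
        raise coxtv.CoxError("no FP candidate converged")
    best = min(usable, key=lambda c: (c.aic, c.transform.m, c.transform.powers))
    return FPSelectionReport(
        variable=variable,
        candidates=candidates,
        best=best,
        aic_null=aic_null,
        aic_linear=linear.aic,
        n_failed=n_failed,
    )


def select_fp_multi(
    intervals_factory: Callable,
    variables: Sequence[str],
    include_fp2: bool = True,
    max_cycles: int = 5,
    eps: float = FP_EPS,
    **fit_kwargs,
) -> dict:
    """Cyclic conditional FP selection over several time-varying covariates.

    ``intervals_factory(transforms: dict[var, FPTransform|None], focus: str)``
    must return ``(intervals, covariate_columns)`` for the model where the
    *focus* variable's candidate columns are appended last and every other
    variable enters through its current transform.  Each variable starts at
    the straight line; one cycle re-selects each variable holding the
    others fixed, and the loop stops when a full cycle changes nothing.

    Returns ``{"transforms": {...}, "reports": {...}, "converged": bool,
    "cycles": int}``.  With a single variable this reduces to
    :func:`select_fp`.
    """
    current: dict[str, FPTransform | None] = {v: FPTransform((1.0,)) for v in variables}
    reports: dict[str, FPSelectionReport] = {}
    converged = False
    cycles = 0
    for cycle in range(max_cycles):
        changed = False
        for var in variables:

            def factory(tr, _var=var):
                trial = dict(current)
                trial[_var] = tr
                return intervals_factory(trial, _var)

            rep = select_fp(
                factory, variable=var, include_fp2=include_fp2, eps=eps, **fit_kwargs
            )
            reports[var] = rep
            if rep.best.transform != current[var]:
                current[var] = rep.best.transform
                changed = True
        cycles = cycle + 1
        if not changed:
            converged = True
            break
    return {
        "transforms": current,
        "reports": reports,
        "converged": converged,
        "cycles": cycles,
    }
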