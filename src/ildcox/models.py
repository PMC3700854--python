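"""Illness-death transition models and hazard-ratio surfaces.

Two model families are provided, both presented statsmodels-style: a model
object built from a subject table whose ``fit()`` returns a results object
with estimates, standard errors, AIC and summary tables.

**Joint approach (J).**  Transitions 1->3 and 2->3 to the absorbing state
share one baseline hazard and one set of fixed-covariate effects gamma; a
time-varying design f(d, t - d), gated by the state indicator 1{t >= d},
carries the change after the intermediate event.  The relation between the
two hazards is c(d, t - d) = exp(beta' f(d, t - d)).  The nested relation
family is

    J.I      c = 1                  (the event changes nothing)
    J.II     c = exp(b0)            (a constant factor)
    J.III.1  c = c(d)               (depends on the waiting time)
    J.III.2  c = c(t - d)           (depends on the sojourn time)
    J.IV     c = c(d, t - d)        (both), canonically
             exp(b0 + b1 d + b2 exp(-(t - d)))
    J.FP     c from a fractional polynomial of t - d (optionally with a
             linear d term)

**Separate approach (S).**  Each transition gets its own Cox model and
baseline; the 2->3 fit is left-truncated at d on the forward clock (or
shifted to the sojourn scale on the reset clock).  The post/pre hazard
ratio lambda_23 / lambda_13 then involves the two smoothed baselines, not
only a parametric c.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.interpolate import make_smoothing_spline

from . import coxtv
from .coxtv import BaselineHazard, CoxFit
from .data import EVENT, SubjectTable
from .fracpoly import FPTransform
from .restructure import (
    D_LINEAR,
    EXP_NEG_SOJOURN,
    INDICATOR,
    FTerm,
    apply_endpoint_convention,
    fp_term,
    term_columns,
    to_joint_layout,
    to_separate_layout,
)

__all__ = [
    "RELATIONS",
    "build_relation",
    "CSurface",
    "HazardRatioSurface",
    "JointIllnessDeathModel",
    "JointIllnessDeathResults",
    "SeparateIllnessDeathModel",
    "SeparateIllnessDeathResults",
    "fit_joint",
    "fit_separate",
    "smooth_hazard",
    "ratio_surface_S",
    "compare_models",
]

RELATIONS = ("J.I", "J.II", "J.III.1", "J.III.2", "J.IV", "J.FP")

#: default evaluation grids (years): waiting times d and sojourn times s
DEFAULT_D_GRID = np.arange(0.25, 5.0 + 1e-9, 0.25)
DEFAULT_S_GRID = np.arange(0.05, 5.0 + 1e-9, 0.05)


def build_relation(
    relation: str,
    fp_transform: FPTransform | None = None,
    include_onset: bool = False,
) -> list[FTerm]:
    """Time-varying term list of one joint-approach relation.

    ``include_onset`` adds the linear waiting-time term alongside the FP of
    the sojourn time for relation J.FP.
    """
    if relation not in RELATIONS:
        raise ValueError(f"unknown relation {relation!r}; choose from {RELATIONS}")
    if (relation == "J.FP") != (fp_transform is not None):
        raise ValueError("fp_transform is required exactly for relation J.FP")
    if relation == "J.I":
        return []
    if relation == "J.II":
        return [INDICATOR]
    if relation == "J.III.1":
        return [INDICATOR, D_LINEAR]
    if relation == "J.III.2":
        return [INDICATOR, EXP_NEG_SOJOURN]
    if relation == "J.IV":
        return [INDICATOR, D_LINEAR, EXP_NEG_SOJOURN]
    terms = [INDICATOR]
    if include_onset:
        terms.append(D_LINEAR)
    terms.append(FTerm("fp", fp_transform, "sojourn"))
    return terms


# ---------------------------------------------------------------------------
# surfaces


@dataclasses.dataclass
class CSurface:
    """Parametric relation c(d, s) = exp(beta' f(d, s)) on a (d, s) grid."""

    d_grid: np.ndarray
    s_grid: np.ndarray
    values: np.ndarray  # shape (len(d_grid), len(s_grid))
    relation: str

    def __post_init__(self):
        self.d_grid = np.asarray(self.d_grid, dtype=float)
        self.s_grid = np.asarray(self.s_grid, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.d_grid), len(self.s_grid)):
            raise ValueError("surface shape does not match the grids")

    def to_frame(self) -> pd.DataFrame:
        dd, ss = np.meshgrid(self.d_grid, self.s_grid, indexing="ij")
        return pd.DataFrame(
            {"d": dd.ravel(), "s": ss.ravel(), "value": self.values.ravel()}
        )

    def plot(self, ax=None, log: bool = True, **kwargs):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        vals = np.log(self.values) if log else self.values
        cs = ax.contourf(self.s_grid, self.d_grid, vals, **kwargs)
        ax.set_xlabel("time since intermediate event s (years)")
        ax.set_ylabel("waiting time d (years)")
        ax.figure.colorbar(cs, ax=ax, label="log c(d, s)" if log else "c(d, s)")
        return ax


@dataclasses.dataclass
class HazardRatioSurface:
    """Estimated post/pre hazard ratio lambda_23(d+s, d) / lambda_13(d+s).

    ``provenance`` records whether the ratio is the closed-form relation of
    approach J or the smoothed-baseline ratio of approach S.  Values are
    NaN (masked) where d + s leaves the support of either baseline.
    """

    d_grid: np.ndarray
    s_grid: np.ndarray
    values: np.ndarray
    provenance: str

    def to_frame(self) -> pd.DataFrame:
        dd, ss = np.meshgrid(self.d_grid, self.s_grid, indexing="ij")
        return pd.DataFrame(
            {"d": dd.ravel(), "s": ss.ravel(), "value": self.values.ravel()}
        )

    def plot(self, ax=None, d_levels: Sequence[float] | None = None, **kwargs):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        levels = d_levels if d_levels is not None else self.d_grid[:: max(1, len(self.d_grid) // 6)]
        for d in levels:
            i = int(np.argmin(np.abs(self.d_grid - d)))
            ax.plot(self.s_grid, self.values[i], label=f"d = {self.d_grid[i]:.2g}", **kwargs)
        ax.set_xlabel("time since intermediate event s (years)")
        ax.set_ylabel("hazard ratio")
        ax.legend()
        return ax


def _c_surface_from_fit(
    fit: CoxFit, f_terms: Sequence[FTerm], relation: str, d_grid, s_grid
) -> CSurface:
    d_grid = np.asarray(d_grid, dtype=float)
    s_grid = np.asarray(s_grid, dtype=float)
    log_c = np.zeros((len(d_grid), len(s_grid)))
    params = fit.params
    for t in f_terms:
        if t.kind == "indicator":
            log_c += params["in_state_2"]
        elif t.kind == "d_linear":
            log_c += np.outer(params["onset_time"] * d_grid, np.ones_like(s_grid))
        elif t.kind == "exp_neg_sojourn":
            log_c += np.outer(
                np.ones_like(d_grid), params["exp_neg_sojourn"] * np.exp(-s_grid)
            )
        else:
            basis = t.transform.basis(
                s_grid if t.variable == "sojourn" else d_grid
            )
            contrib = basis @ params[t.columns()].to_numpy()
            if t.variable == "sojourn":
                log_c += np.outer(np.ones_like(d_grid), contrib)
            else:
                log_c += np.outer(contrib, np.ones_like(s_grid))
    return CSurface(d_grid, s_grid, np.exp(log_c), relation)


# ---------------------------------------------------------------------------
# joint approach


class JointIllnessDeathModel:
    """Joint-approach model: shared 1->3 / 2->3 hazard with relation c.

    Parameters
    ----------
    subjects : SubjectTable
        The cohort; the endpoint convention is applied on construction
        unless ``apply_convention=False``.
    relation : one of ``RELATIONS``.
    endpoint : "overall_survival" or "distant_disease_free".
    covariates : time-fixed covariate columns entering all transitions
        (default: every covariate of the table).
    fp_transform : FPTransform, required iff relation == "J.FP".
    include_onset : keep the linear d term alongside the FP (J.FP only).
    split_times : explicit cut grid; default cuts post-event rows at the
        observed event times when a continuously varying term is present.
    """

    def __init__(
        self,
        subjects: SubjectTable,
        relation: str = "J.IV",
        endpoint: str = "overall_survival",
        covariates: Sequence[str] | None = None,
        fp_transform: FPTransform | None = None,
        include_onset: bool = False,
        split_times: Sequence[float] | None = None,
        apply_convention: bool = True,
    ):
        if apply_convention:
            subjects = apply_endpoint_convention(subjects, endpoint)
        self.subjects = subjects
        self.relation = relation
        self.endpoint = endpoint
        self.covariates = list(
            subjects.covariates if covariates is None else covariates
        )
        self.f_terms = build_relation(relation, fp_transform, include_onset)
        self.split_times = split_times
        self.layout, self.layout_12 = to_joint_layout(
            subjects, self.f_terms, split_times
        )

    @classmethod
    def from_dataframe(
        cls, df: pd.DataFrame, covariates: Sequence[str] | None = None, **kwargs
    ) -> "JointIllnessDeathModel":
        return cls(SubjectTable(df, covariates), **kwargs)

    @property
    def design_columns(self) -> list[str]:
        return term_columns(self.f_terms) + self.covariates

    def fit(self, ties_method: str = "efron", **fit_kwargs) -> "JointIllnessDeathResults":
        fit = coxtv.fit_cox(
            self.layout, self.design_columns, ties_method=ties_method, **fit_kwargs
        )
        try:
            fit_12 = coxtv.fit_cox(
                self.layout_12, self.covariates, ties_method=ties_method, **fit_kwargs
            )
        except coxtv.CoxError:
            fit_12 = None
        return JointIllnessDeathResults(self, fit, fit_12)


@dataclasses.dataclass
class JointIllnessDeathResults:
    """Results of a joint-approach fit.

    ``fit`` carries beta (time-varying terms) and the shared gamma;
    ``fit_12`` is the separately fitted 1->2 model with its own gamma_12
    (None when the cohort has no intermediate events).
    """

    model: JointIllnessDeathModel
    fit: CoxFit
    fit_12: CoxFit | None

    approach = "J"

    @property
    def params(self) -> pd.Series:
        return self.fit.params

    @property
    def bse(self) -> pd.Series:
        return self.fit.bse

    @property
    def llf(self) -> float:
        return self.fit.log_pl

    @property
    def aic(self) -> float:
        return self.fit.aic

    @property
    def relation(self) -> str:
        return self.model.relation

    @property
    def endpoint(self) -> str:
        return self.model.endpoint

    def baseline(self) -> BaselineHazard:
        return coxtv.breslow_baseline(self.fit, self.model.layout)

    def c_surface(self, d_grid=None, s_grid=None) -> CSurface:
        """The fitted relation c(d, s) = exp(beta' f(d, s)) on a grid."""
        d_grid = DEFAULT_D_GRID if d_grid is None else d_grid
        s_grid = DEFAULT_S_GRID if s_grid is None else s_grid
        return _c_surface_from_fit(
            self.fit, self.model.f_terms, self.relation, d_grid, s_grid
        )

    def summary(self) -> str:
        lines = [
            f"Joint illness-death model  (relation {self.relation}, "
            f"endpoint {self.endpoint})",
            f"rows {self.fit.n_rows}, events {self.fit.n_events}, "
            f"log PL {self.llf:.4f}, AIC {self.aic:.2f}, "
            f"converged {self.fit.converged} ({self.fit.n_iter} it)",
            "",
            "Shared 1->3 / 2->3 hazard:",
            self.fit.summary().to_string(float_format=lambda v: f"{v:.4f}"),
        ]
        if self.fit_12 is not None and self.fit_12.k:
            lines += [
                "",
                "Transition 1->2:",
                self.fit_12.summary().to_string(float_format=lambda v: f"{v:.4f}"),
            ]
        return "\n".join(lines)


def fit_joint(
    subjects: SubjectTable,
    relation: str = "J.IV",
    endpoint: str = "overall_survival",
    fp_transform: FPTransform | None = None,
    **kwargs,
) -> JointIllnessDeathResults:
    """Convenience wrapper: build and fit a joint-approach model."""
    fit_kwargs = {
        k: kwargs.pop(k) for k in ("ties_method", "tol", "max_iter") if k in kwargs
    }
    model = JointIllnessDeathModel(
        subjects, relation=relation, endpoint=endpoint, fp_transform=fp_transform, **kwargs
    )
    return model.fit(**fit_kwargs)


# ---------------------------------------------------------------------------
# separate approach


class SeparateIllnessDeathModel:
    """Separate-approach model: per-transition Cox fits.

    ``f_terms`` enter the 2->3 design (the waiting time d is available as
    the fixed covariate ``onset_time``); the indicator is dropped there
    since every 2->3 row is post-event (it would be constant).
    """

    def __init__(
        self,
        subjects: SubjectTable,
        endpoint: str = "overall_survival",
        clock: str = "forward",
        f_terms: Sequence[FTerm] = (D_LINEAR, EXP_NEG_SOJOURN),
        covariates: Sequence[str] | None = None,
        split_times: Sequence[float] | None = None,
        apply_convention: bool = True,
    ):
        if apply_convention:
            subjects = apply_endpoint_convention(subjects, endpoint)
        self.subjects = subjects
        self.endpoint = endpoint
        self.clock = clock
        self.f_terms = [t for t in f_terms if t.kind != "indicator"]
        self.covariates = list(
            subjects.covariates if covariates is None else covariates
        )
        self.layouts = {
            "12": to_separate_layout(subjects, "12"),
            "13": to_separate_layout(subjects, "13"),
            "23": to_separate_layout(
                subjects, "23", clock=clock, f_terms=self.f_terms, split_times=split_times
            ),
        }

    @classmethod
    def from_dataframe(
        cls, df: pd.DataFrame, covariates: Sequence[str] | None = None, **kwargs
    ) -> "SeparateIllnessDeathModel":
        return cls(SubjectTable(df, covariates), **kwargs)

    def design_columns(self, transition: str) -> list[str]:
        if transition == "23":
            return term_columns(self.f_terms) + self.covariates
        return list(self.covariates)

    def fit(self, ties_method: str = "efron", **fit_kwargs) -> "SeparateIllnessDeathResults":
        k23 = len(self.design_columns("23"))
        n23 = int(self.layouts["23"]["status"].sum()) if len(self.layouts["23"]) else 0
        if n23 < k23 + 5:
            raise coxtv.CoxError(
                f"too few 2->3 events ({n23}) for {k23} coefficients; "
                "need at least k + 5"
            )
        fits = {}
        for trans in ("12", "13", "23"):
            fits[trans] = coxtv.fit_cox(
                self.layouts[trans],
                self.design_columns(trans),
                ties_method=ties_method,
                **fit_kwargs,
            )
        baselines = {
            trans: coxtv.breslow_baseline(fits[trans], self.layouts[trans])
            for trans in ("13", "23")
        }
        return SeparateIllnessDeathResults(self, fits, baselines)


@dataclasses.dataclass
class SeparateIllnessDeathResults:
    """Per-transition fits (gamma_12, gamma_13, gamma_23 unconstrained)."""

    model: SeparateIllnessDeathModel
    fits: Mapping[str, CoxFit]
    baselines: Mapping[str, BaselineHazard]

    approach = "S"

    @property
    def endpoint(self) -> str:
        return self.model.endpoint

    @property
    def aic(self) -> dict:
        return {t: f.aic for t, f in self.fits.items()}

    def hazard_ratio_surface(
        self,
        d_grid=None,
        s_grid=None,
        reference_z: Mapping[str, float] | None = None,
        lam: float | None = 1.0,
    ) -> HazardRatioSurface:
        return ratio_surface_S(self, d_grid, s_grid, reference_z, lam=lam)

    def summary(self) -> str:
        lines = [
            f"Separate illness-death models  (clock {self.model.clock}, "
            f"endpoint {self.endpoint})"
        ]
        for trans in ("12", "13", "23"):
            f = self.fits[trans]
            lines += [
                "",
                f"Transition {trans[0]}->{trans[1]}: events {f.n_events}, "
                f"log PL {f.log_pl:.4f}, AIC {f.aic:.2f}",
            ]
            if f.k:
                lines.append(f.summary().to_string(float_format=lambda v: f"{v:.4f}"))
        return "\n".join(lines)


def fit_separate(
    subjects: SubjectTable,
    endpoint: str = "overall_survival",
    clock: str = "forward",
    f_terms: Sequence[FTerm] = (D_LINEAR, EXP_NEG_SOJOURN),
    **kwargs,
) -> SeparateIllnessDeathResults:
    """Convenience wrapper: build and fit the separate-approach models."""
    fit_kwargs = {
        k: kwargs.pop(k) for k in ("ties_method", "tol", "max_iter") if k in kwargs
    }
    model = SeparateIllnessDeathModel(
        subjects, endpoint=endpoint, clock=clock, f_terms=f_terms, **kwargs
    )
    return model.fit(**fit_kwargs)


# ---------------------------------------------------------------------------
# baseline smoothing and the approach-S surface


@dataclasses.dataclass
class SmoothedHazard:
    """Smoothed hazard lambda_0(t): spline derivative of the cumulative."""

    grid: np.ndarray
    hazard: np.ndarray
    support: tuple

    def __call__(self, t):
        t = np.asarray(t, dtype=float)
        out = np.interp(t, self.grid, self.hazard, left=np.nan, right=np.nan)
        return out


def smooth_hazard(
    baseline: BaselineHazard,
    lam: float | None = 1.0,
    grid: np.ndarray | None = None,
    n_grid: int = 200,
    floor: float = 1e-8,
) -> SmoothedHazard:
    """Smooth a cumulative baseline hazard and differentiate it.

    A cubic smoothing spline is fitted to the Breslow cumulative hazard at
    the event times and its first derivative is
    evaluated on an equispaced grid spanning the central 90% of event
    times.  Negative derivative values are clamped to ``floor`` with a
    warning.

    The penalty defaults to a fixed ``lam`` of 1.0 (times in years,
    cumulative hazards of order one): the jumps of a cumulative hazard are
    martingale increments, whose serial dependence makes generalised
    cross-validation (``lam=None``) undersmooth badly, so GCV is available
    but not the default.
    """
    t = baseline.event_times
    y = baseline.cumulative
    if len(t) < 10:
        raise ValueError(
            f"need at least 10 event times to smooth a hazard, got {len(t)}; "
            "use a coarser model or more data"
        )
    spl = make_smoothing_spline(t, y, lam=lam)
    if grid is None:
        lo, hi = np.quantile(t, [0.05, 0.95])
        grid = np.linspace(lo, hi, n_grid)
    deriv = spl.derivative()(grid)
    if np.any(deriv < 0):
        warnings.warn(
            "smoothed cumulative hazard locally decreasing; derivative clamped",
            RuntimeWarning,
        )
        deriv = np.maximum(deriv, floor)
    return SmoothedHazard(np.asarray(grid), deriv, (float(grid[0]), float(grid[-1])))


def ratio_surface_S(
    results: SeparateIllnessDeathResults,
    d_grid=None,
    s_grid=None,
    reference_z: Mapping[str, float] | None = None,
    lam: float | None = 1.0,
) -> HazardRatioSurface:
    """Hazard-ratio surface lambda_23(d+s, d) / lambda_13(d+s), approach S.

    Uses the smoothed baselines of both transitions and the fitted
    coefficients at a reference covariate pattern (default: all zeros).
    Requires the 2->3 fit on the forward clock, so numerator and
    denominator share the time axis at t = d + s; points where d + s
    leaves either baseline's support are masked (NaN), never extrapolated.
    """
    if results.model.clock != "forward":
        raise ValueError(
            "the hazard-ratio surface needs the 2->3 fit on the forward clock; "
            "reset-clock axes are not comparable to the 1->3 time axis"
        )
    d_grid = DEFAULT_D_GRID if d_grid is None else np.asarray(d_grid, dtype=float)
    s_grid = DEFAULT_S_GRID if s_grid is None else np.asarray(s_grid, dtype=float)
    z = dict(reference_z or {})

    h13 = smooth_hazard(results.baselines["13"], lam=lam)
    h23 = smooth_hazard(results.baselines["23"], lam=lam)

    fit13, fit23 = results.fits["13"], results.fits["23"]
    zcols = results.model.covariates
    lin13 = sum(fit13.params.get(c, 0.0) * z.get(c, 0.0) for c in zcols)
    lin23 = sum(fit23.params.get(c, 0.0) * z.get(c, 0.0) for c in zcols)

    dd, ss = np.meshgrid(d_grid, s_grid, indexing="ij")
    tt = dd + ss
    base13 = h13(tt)
    base23 = h23(tt)

    log_f = np.zeros_like(tt)
    params = fit23.params
    for term in results.model.f_terms:
        if term.kind == "d_linear":
            log_f += params["onset_time"] * dd
        elif term.kind == "exp_neg_sojourn":
            log_f += params["exp_neg_sojourn"] * np.exp(-ss)
        elif term.kind == "fp":
            x = ss if term.variable == "sojourn" else dd
            basis = term.transform.basis(np.maximum(x.ravel(), 1e-12))
            log_f += (basis @ params[term.columns()].to_numpy()).reshape(tt.shape)

    values = base23 * np.exp(log_f + lin23) / (base13 * np.exp(lin13))
    return HazardRatioSurface(d_grid, s_grid, values, provenance="S")


# ---------------------------------------------------------------------------
# model comparison


def compare_models(results: Sequence[JointIllnessDeathResults]) -> pd.DataFrame:
    """AIC table over joint-approach fits of the same cohort and endpoint.

    Cross-approach comparison (J vs S) is refused: the two approaches
    condition on different event sets, so their partial likelihoods are
    not on a common scale.
    """
    if not results:
        raise ValueError("no fits to compare")
    for r in results:
        if getattr(r, "approach", None) != "J":
            raise ValueError(
                "AIC comparison is defined within approach J only; "
                "separate-approach fits use a different likelihood factorisation"
            )
    endpoints = {r.endpoint for r in results}
    if len(endpoints) > 1:
        raise ValueError(f"fits mix endpoints {sorted(endpoints)}")
    rows = [
        {
            "relation": r.relation,
            "k": r.fit.k,
            "log_pl": r.llf,
            "aic": r.aic,
        }
        for r in results
    ]
    df = pd.DataFrame(rows).sort_values("aic").reset_index(drop=True)
    df["delta_aic"] = df["aic"] - df["aic"].min()
    return df
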