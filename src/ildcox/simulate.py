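"""Illness-death cohort simulator with sojourn-time-dependent 2->3 hazards.

Subjects start in the healthy state with time-fixed covariates z.  Latent
times to the intermediate event (1->2) and to the absorbing event without
it (1->3) are drawn by cumulative-hazard inversion from proportional-
hazards models with constant or Weibull baselines.  A subject reaching the
intermediate state at time d then faces the hazard

    lambda_23(t) = lambda_0,23(t) * c(d, t - d) * exp(gamma_23' z),  t > d,

where the multiplier c is 1 (none), the exponential-decay form
exp(beta0 + beta1 * d + beta2 * exp(-(t - d))), or an FP-based form
exp(sum_j beta_j * (t - d)^(p_j)).  The 2->3 time is drawn by numerical
inversion of the integrated hazard.  Censoring is administrative at a
horizon tau and/or exponential.

Random streams are split per subject from the master seed, so a cohort is
reproducible independently of generation order.
"""

from __future__ import annotations

import dataclasses
import json
import math
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import cumulative_trapezoid
from scipy.optimize import brentq

from .data import CENSORED, EVENT, SubjectTable
from .fracpoly import FP_EPS, FPTransform

__all__ = [
    "Baseline",
    "CSpec",
    "SimConfig",
    "simulate_cohort",
    "inversion_sample",
]


@dataclasses.dataclass(frozen=True)
class Baseline:
    """Constant or Weibull baseline hazard for one transition.

    ``constant``: hazard ``rate``; ``weibull``: hazard
    (shape/scale) * (t/scale)^(shape-1), so shape 1 recovers the constant
    1/scale.
    """

    kind: str = "constant"
    rate: float = 0.1
    shape: float = 1.0
    scale: float = 1.0

    def __post_init__(self):
        if self.kind not in ("constant", "weibull"):
            raise ValueError(f"unknown baseline kind {self.kind!r}")
        if self.kind == "constant" and self.rate <= 0:
            raise ValueError("constant baseline needs rate > 0")
        if self.kind == "weibull" and (self.shape <= 0 or self.scale <= 0):
            raise ValueError("weibull baseline needs shape, scale > 0")

    def hazard(self, t):
        t = np.asarray(t, dtype=float)
        if self.kind == "constant":
            return np.full_like(t, self.rate)
        return (self.shape / self.scale) * (t / self.scale) ** (self.shape - 1.0)

    def cumhaz(self, t):
        t = np.asarray(t, dtype=float)
        if self.kind == "constant":
            return self.rate * t
        return (t / self.scale) ** self.shape

    def inv_cumhaz(self, h):
        h = np.asarray(h, dtype=float)
        if self.kind == "constant":
            return h / self.rate
        return self.scale * h ** (1.0 / self.shape)


@dataclasses.dataclass(frozen=True)
class CSpec:
    """Multiplier c(d, t - d) applied to the 2->3 hazard.

    ``none``: c = 1.  ``exp_decay``: c = exp(b0 + b1 d + b2 exp(-(t-d))).
    ``fp``: c = exp(sum_j betas[j] * basis_j(t - d)) for an FP with the
    given powers (with the package's origin shift near zero sojourns).
    """

    kind: str = "none"
    b0: float = 0.0
    b1: float = 0.0
    b2: float = 0.0
    powers: tuple = ()
    betas: tuple = ()

    def __post_init__(self):
        if self.kind not in ("none", "exp_decay", "fp"):
            raise ValueError(f"unknown c-spec kind {self.kind!r}")
        if self.kind == "fp" and len(self.powers) != len(self.betas):
            raise ValueError("fp c-spec needs one beta per power")

    def log_c(self, d: float, s: np.ndarray) -> np.ndarray:
        s = np.asarray(s, dtype=float)
        if self.kind == "none":
            return np.zeros_like(s)
        if self.kind == "exp_decay":
            return self.b0 + self.b1 * d + self.b2 * np.exp(-s)
        tr = FPTransform(tuple(self.powers)) if len(self.powers) in (1, 2) else None
        if tr is not None:
            basis = tr.basis(np.maximum(s, 1e-12), eps=FP_EPS)
            return basis @ np.asarray(self.betas, dtype=float)
        # more than two powers: plain power sum with the same shift rule
        out = np.zeros_like(s)
        shifted = np.maximum(s, 1e-12) + FP_EPS
        for p, b in zip(self.powers, self.betas):
            out += b * (np.log(shifted) if p == 0 else shifted ** p)
        return out

    @property
    def f_terms_hint(self) -> list[str]:
        if self.kind == "none":
            return []
        if self.kind == "exp_decay":
            return ["indicator", "d_linear", "exp_neg_sojourn"]
        return ["indicator", f"fp{self.powers}"]


@dataclasses.dataclass
class SimConfig:
    """Generative configuration of one illness-death cohort.

    Defaults mirror a breast-cancer-like cohort: a five-year administrative
    horizon with light random censoring, roughly one subject in eight
    reaching the intermediate state, and two prognostic covariates (one
    standard normal, one balanced binary).
    """

    n: int = 1000
    baseline12: Baseline = Baseline("constant", rate=0.035)
    baseline13: Baseline = Baseline("constant", rate=0.06)
    baseline23: Baseline = Baseline("constant", rate=0.06)
    gamma12: Sequence[float] = (0.0, 0.0)
    gamma13: Sequence[float] = (0.0, 0.0)
    gamma23: Sequence[float] = (0.0, 0.0)
    covariates: Sequence[tuple] = (("z_cont", "normal"), ("z_bin", "binary"))
    c_spec: CSpec = CSpec("none")
    horizon: float = 5.0
    censor_rate: float = 0.02
    seed: int = 0

    def __post_init__(self):
        if self.n < 1:
            raise ValueError("n >= 1 required")
        if self.horizon <= 0:
            raise ValueError("horizon > 0 required")
        self.covariates = tuple(tuple(c) for c in self.covariates)
        self.gamma12 = tuple(float(g) for g in self.gamma12)
        self.gamma13 = tuple(float(g) for g in self.gamma13)
        self.gamma23 = tuple(float(g) for g in self.gamma23)
        k = len(self.covariates)
        for g in (self.gamma12, self.gamma13, self.gamma23):
            if len(g) != k:
                raise ValueError("gamma vectors must match the covariate list")

    @property
    def covariate_names(self) -> list[str]:
        return [name for name, _ in self.covariates]

    @classmethod
    def from_dict(cls, payload: Mapping) -> "SimConfig":
        kw = dict(payload)
        for key in ("baseline12", "baseline13", "baseline23"):
            if key in kw and isinstance(kw[key], Mapping):
                kw[key] = Baseline(**kw[key])
        if "c_spec" in kw and isinstance(kw["c_spec"], Mapping):
            spec = dict(kw["c_spec"])
            for tup in ("powers", "betas"):
                if tup in spec:
                    spec[tup] = tuple(spec[tup])
            kw["c_spec"] = CSpec(**spec)
        if "covariates" in kw:
            kw["covariates"] = [tuple(c) for c in kw["covariates"]]
        return cls(**kw)

    def to_dict(self) -> dict:
        out = dataclasses.asdict(self)
        out["covariates"] = [list(c) for c in self.covariates]
        return out


def inversion_sample(
    cumhaz: Callable[[float], float],
    u: float,
    t_min: float = 0.0,
    t_max: float = np.inf,
    tol: float = 1e-10,
) -> float:
    """Solve cumhaz(t) = -log(u) for t by bracketing + Brent's method.

    ``cumhaz`` must be non-decreasing with cumhaz(t_min) = 0.  Returns
    ``t_max`` (the censor sentinel) if the target is not reached by then.
    """
    target = -math.log(u)
    if target <= 0:
        return t_min
    if cumhaz(t_min) > tol:
        raise ValueError("cumhaz(t_min) must be 0")
    lo, hi = t_min, min(t_min + 1.0, t_max)
    prev = 0.0
    while True:
        val = cumhaz(hi)
        if val < prev - tol:
            raise ValueError("cumhaz is not non-decreasing")
        prev = val
        if val >= target or hi >= t_max:
            break
        lo = hi
        hi = min(t_min + 2.0 * (hi - t_min), t_max)
    if prev < target:
        return t_max
    return float(brentq(lambda t: cumhaz(t) - target, lo, hi, xtol=tol))


def _draw_covariates(rng: np.random.Generator, spec: Sequence[tuple]) -> np.ndarray:
    vals = []
    for _, kind in spec:
        if kind == "normal":
            vals.append(rng.standard_normal())
        elif kind == "binary":
            vals.append(float(rng.integers(0, 2)))
        else:
            raise ValueError(f"unknown covariate generator {kind!r}")
    return np.array(vals)


#: sojourn-time grid resolution (years) for the integrated 2->3 hazard
_GRID_STEP = 1.0 / 500.0


def _sample_sojourn(
    cfg: SimConfig, d: float, z: np.ndarray, u: float
) -> float:
    """Time from d to the 2->3 event (on the sojourn scale), or inf.

    The integrated hazard H(s) = int_0^s lambda_0,23(d+v) c(d, v)
    exp(g'z) dv is tabulated on a fine grid up to 10x the horizon and
    inverted by monotone interpolation; constant-baseline/no-multiplier
    cases use the closed form.
    """
    lin = float(np.dot(cfg.gamma23, z))
    target = -math.log(u)
    if cfg.c_spec.kind == "none" and cfg.baseline23.kind == "constant":
        rate = cfg.baseline23.rate * math.exp(lin)
        return target / rate
    s_max = 10.0 * cfg.horizon
    grid = np.arange(0.0, s_max + _GRID_STEP, _GRID_STEP)
    log_haz = (
        np.log(np.maximum(cfg.baseline23.hazard(d + grid), 1e-300))
        + cfg.c_spec.log_c(d, grid)
        + lin
    )
    H = cumulative_trapezoid(np.exp(log_haz), grid, initial=0.0)
    if H[-1] < target:
        return math.inf
    j = int(np.searchsorted(H, target))
    # linear interpolation inside the bracketing grid cell
    h0, h1 = H[j - 1], H[j]
    frac = 0.0 if h1 == h0 else (target - h0) / (h1 - h0)
    return float(grid[j - 1] + frac * _GRID_STEP)


def simulate_cohort(config: SimConfig) -> tuple[SubjectTable, dict]:
    """Simulate one cohort; returns the subject table and the truth record.

    The truth record holds the full configuration, the seed, and each
    subject's latent times (before censoring), so downstream tests never
    re-derive the truth from the observed data.
    """
    cfg = config
    streams = np.random.SeedSequence(cfg.seed).spawn(cfg.n)
    names = cfg.covariate_names
    rows = []
    latents = []
    for i in range(cfg.n):
        rng = np.random.default_rng(streams[i])
        z = _draw_covariates(rng, cfg.covariates)
        u12, u13, u23, uc = rng.uniform(size=4)
        t12 = float(cfg.baseline12.inv_cumhaz(-math.log(u12) * math.exp(-float(np.dot(cfg.gamma12, z)))))
        t13 = float(cfg.baseline13.inv_cumhaz(-math.log(u13) * math.exp(-float(np.dot(cfg.gamma13, z)))))
        t_cens = cfg.horizon
        if cfg.censor_rate > 0:
            t_cens = min(t_cens, -math.log(uc) / cfg.censor_rate)

        d = None
        t23 = None
        if t12 < min(t13, t_cens):
            d = t12
            s = _sample_sojourn(cfg, d, z, u23)
            t23 = d + s if math.isfinite(s) else math.inf
            exit_time = min(t23, t_cens)
            status = EVENT if t23 <= t_cens else CENSORED
            if not math.isfinite(exit_time):  # unreachable hazard: censor at horizon
                exit_time, status = cfg.horizon, CENSORED
        else:
            exit_time = min(t13, t_cens)
            status = EVENT if t13 <= t_cens else CENSORED

        rec = {
            "id": i,
            "entry": 0.0,
            "d": np.nan if d is None else d,
            "dd_time": np.nan,
            "time": exit_time,
            "status": status,
        }
        rec.update(dict(zip(names, z)))
        rows.append(rec)
        latents.append(
            {
                "id": i,
                "t12": t12,
                "t13": t13,
                "t23": None if t23 is None or not math.isfinite(t23) else t23,
                "censor": t_cens,
            }
        )
    table = SubjectTable(pd.DataFrame(rows), names)
    truth = {"config": cfg.to_dict(), "seed": cfg.seed, "latent_times": latents}
    return table, truth


def write_truth(truth: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(truth, fh, indent=2)
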