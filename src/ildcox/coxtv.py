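"""Cox proportional-hazards engine for start-stop (counting-process) data.

The partial likelihood is evaluated on half-open at-risk intervals
(start, stop]: a row is in the risk set of an event at time u iff
start < u <= stop, which handles both time-varying covariates (a subject
contributes several rows) and left truncation (delayed entry) without
special cases.  Ties are handled by the Efron correction (default) or the
Breslow approximation.  Maximisation is Newton-Raphson with step-halving;
the covariance is the inverse observed information at the optimum.

Risk-set sums are accumulated with difference arrays over the sorted event
times, so one likelihood/gradient/Hessian evaluation is O(rows * p^2)
regardless of the number of events.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CoxError",
    "CoxFit",
    "BaselineHazard",
    "log_partial_likelihood",
    "fit_cox",
    "breslow_baseline",
    "lr_test",
    "backward_eliminate",
]

#: |beta| beyond which a still-climbing likelihood is declared monotone
MONOTONE_BETA = 20.0


class CoxError(ValueError):
    """Raised for invalid fitting problems (no events, rank deficiency...)."""


@dataclasses.dataclass
class BaselineHazard:
    """Breslow baseline hazard: jumps dLambda0 at the observed event times."""

    event_times: np.ndarray
    increments: np.ndarray
    cumulative: np.ndarray = None

    def __post_init__(self):
        self.event_times = np.asarray(self.event_times, dtype=float)
        self.increments = np.asarray(self.increments, dtype=float)
        if np.any(self.increments < 0):
            raise ValueError("baseline increments must be non-negative")
        if self.cumulative is None:
            self.cumulative = np.cumsum(self.increments)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time": self.event_times,
                "increment": self.increments,
                "cumulative": self.cumulative,
            }
        )


@dataclasses.dataclass
class CoxFit:
    """Result of a partial-likelihood fit.

    Coefficient names follow the design columns: beta for time-varying
    terms, gamma for the time-fixed covariates of whichever transition the
    layout encodes.
    """

    names: list[str]
    coefficients: np.ndarray
    covariance: np.ndarray
    log_pl: float
    log_pl_null: float
    k: int
    ties_method: str
    converged: bool
    n_iter: int
    n_events: int
    n_rows: int
    message: str = ""

    @property
    def aic(self) -> float:
        return -2.0 * self.log_pl + 2.0 * self.k

    @property
    def params(self) -> pd.Series:
        return pd.Series(self.coefficients, index=self.names, name="coef")

    @property
    def bse(self) -> pd.Series:
        return pd.Series(np.sqrt(np.diag(self.covariance)), index=self.names, name="se")

    def wald_z(self) -> pd.Series:
        se = self.bse
        return self.params / se.replace(0.0, np.nan)

    def wald_p(self) -> pd.Series:
        z = self.wald_z()
        return pd.Series(2 * stats.norm.sf(np.abs(z)), index=self.names, name="p")

    def confint(self, alpha: float = 0.05) -> pd.DataFrame:
        q = stats.norm.ppf(1 - alpha / 2)
        se = self.bse
        return pd.DataFrame(
            {"lower": self.params - q * se, "upper": self.params + q * se}
        )

    def summary(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "coef": self.params,
                "exp(coef)": np.exp(self.params),
                "se": self.bse,
                "z": self.wald_z(),
                "p": self.wald_p(),
            }
        )
        return df

    def to_json(self) -> str:
        return json.dumps(
            {
                "coefficients": dict(zip(self.names, self.coefficients.tolist())),
                "se": dict(zip(self.names, self.bse.tolist())),
                "covariance": self.covariance.tolist(),
                "log_pl": self.log_pl,
                "log_pl_null": self.log_pl_null,
                "k": self.k,
                "aic": self.aic,
                "ties_method": self.ties_method,
                "converged": self.converged,
                "n_iter": self.n_iter,
                "n_events": self.n_events,
                "n_rows": self.n_rows,
                "message": self.message,
            },
            indent=2,
        )


# ---------------------------------------------------------------------------
# likelihood internals


class _CoxData:
    """Preprocessed design: event-time indexing shared by all evaluations."""

    def __init__(self, intervals: pd.DataFrame, covariates: Sequence[str]):
        for c in ("start", "stop", "status"):
            if c not in intervals.columns:
                raise CoxError(f"interval table lacks column {c!r}")
        self.names = list(covariates)
        self.start = intervals["start"].to_numpy(dtype=float)
        self.stop = intervals["stop"].to_numpy(dtype=float)
        self.status = intervals["status"].to_numpy(dtype=int)
        if np.any(self.stop <= self.start):
            raise CoxError("intervals must satisfy start < stop")
        self.X = (
            intervals.loc[:, self.names].to_numpy(dtype=float)
            if self.names
            else np.empty((len(self.start), 0))
        )
        ev = self.status == 1
        self.n_events = int(ev.sum())
        if self.n_events == 0:
            raise CoxError("no events in the data; partial likelihood undefined")
        self.event_rows = np.flatnonzero(ev)
        self.event_times = np.unique(self.stop[self.event_rows])
        E = len(self.event_times)
        # risk-set index range [lo, hi) over the sorted event times
        self.lo = np.searchsorted(self.event_times, self.start, side="right")
        self.hi = np.searchsorted(self.event_times, self.stop, side="right")
        self.ev_group = np.searchsorted(self.event_times, self.stop[self.event_rows])
        self.m = np.bincount(self.ev_group, minlength=E).astype(float)
        self.max_m = int(self.m.max())
        self.E = E
        self.p = self.X.shape[1]
        # event-weighted covariate means, used for centering
        self.xbar = self.X[self.event_rows].mean(axis=0) if self.p else np.zeros(0)

    # -- range accumulation over event-time indices -------------------
    def _range_sum(self, weights: np.ndarray) -> np.ndarray:
        """sum of per-row weights over every event time's risk set.

        Each row covers the contiguous index range [lo, hi); accumulate a
        difference array with bincount and integrate.
        """
        E = self.E
        if weights.ndim == 1:
            acc = np.bincount(self.lo, weights=weights, minlength=E + 1)
            acc -= np.bincount(self.hi, weights=weights, minlength=E + 1)
            return np.cumsum(acc)[:E]
        out = np.empty((E, weights.shape[1]))
        for j in range(weights.shape[1]):
            acc = np.bincount(self.lo, weights=weights[:, j], minlength=E + 1)
            acc -= np.bincount(self.hi, weights=weights[:, j], minlength=E + 1)
            out[:, j] = np.cumsum(acc)[:E]
        return out

    def _weights(self, beta: np.ndarray, center: bool) -> tuple[np.ndarray, np.ndarray]:
        Xc = self.X - self.xbar if center else self.X
        eta = Xc @ beta if self.p else np.zeros(len(self.start))
        return Xc, np.exp(eta)

    def loglik(self, beta: np.ndarray, ties: str, center: bool = True) -> float:
        Xc, w = self._weights(beta, center)
        S0 = self._range_sum(w)
        eta_ev = (Xc[self.event_rows] @ beta) if self.p else np.zeros(self.n_events)
        ll = float(eta_ev.sum())
        if ties == "breslow" or self.max_m == 1:
            ll -= float((self.m * np.log(S0)).sum())
            return ll
        S0D = np.bincount(self.ev_group, weights=w[self.event_rows], minlength=self.E)
        for r in range(self.max_m):
            active = self.m > r
            frac = np.zeros(self.E)
            frac[active] = r / self.m[active]
            denom = S0 - frac * S0D
            ll -= float(np.log(denom[active]).sum())
        return ll

    def loglik_grad_info(
        self, beta: np.ndarray, ties: str, center: bool = True
    ) -> tuple[float, np.ndarray, np.ndarray]:
        Xc, w = self._weights(beta, center)
        p = self.p
        S0 = self._range_sum(w)
        wX = w[:, None] * Xc
        S1 = self._range_sum(wX)
        # symmetric second moments, accumulated pairwise
        S2 = np.zeros((self.E, p, p))
        for j in range(p):
            col = self._range_sum(wX[:, j : j + 1] * Xc[:, j:])[:, :]
            S2[:, j, j:] = col
            S2[:, j:, j] = col.reshape(self.E, -1)
        ev = self.event_rows
        eta_ev = (Xc[ev] @ beta) if p else np.zeros(self.n_events)
        ll = float(eta_ev.sum())
        grad = Xc[ev].sum(axis=0)
        info = np.zeros((p, p))

        efron = ties == "efron" and self.max_m > 1
        if efron:
            S0D = np.bincount(self.ev_group, weights=w[ev], minlength=self.E)
            S1D = np.zeros((self.E, p))
            np.add.at(S1D, self.ev_group, wX[ev])
            S2D = np.zeros((self.E, p, p))
            np.add.at(S2D, self.ev_group, wX[ev][:, :, None] * Xc[ev][:, None, :])
            for r in range(self.max_m):
                active = self.m > r
                frac = np.zeros(self.E)
                frac[active] = r / self.m[active]
                denom = S0 - frac * S0D
                num1 = S1 - frac[:, None] * S1D
                num2 = S2 - frac[:, None, None] * S2D
                g = num1[active] / denom[active, None]
                ll -= float(np.log(denom[active]).sum())
                grad -= g.sum(axis=0)
                info += (num2[active] / denom[active, None, None]).sum(axis=0)
                info -= np.einsum("ij,ik->jk", g, g)
        else:
            g = S1 / S0[:, None]
            ll -= float((self.m * np.log(S0)).sum())
            grad -= (self.m[:, None] * g).sum(axis=0)
            info += (self.m[:, None, None] * S2 / S0[:, None, None]).sum(axis=0)
            info -= np.einsum("i,ij,ik->jk", self.m, g, g)
        return ll, grad, info


def log_partial_likelihood(
    intervals: pd.DataFrame,
    coefficients: Sequence[float] | dict,
    covariates: Sequence[str] | None = None,
    ties_method: str = "efron",
) -> float:
    """Log partial likelihood of a start-stop layout at given coefficients.

    ``coefficients`` may be a mapping {column: value} or a vector aligned
    with ``covariates``.
    """
    if isinstance(coefficients, dict):
        covariates = list(coefficients)
        beta = np.array([coefficients[c] for c in covariates], dtype=float)
    else:
        beta = np.asarray(coefficients, dtype=float)
        if covariates is None:
            raise CoxError("covariate names required with a coefficient vector")
    data = _CoxData(intervals, covariates or [])
    if data.p != len(beta):
        raise CoxError("coefficient vector does not match covariates")
    return data.loglik(beta, ties_method, center=False)


def _check_rank(data: _CoxData) -> None:
    if data.p == 0:
        return
    Xc = data.X - data.X.mean(axis=0)
    # rank of the design; name columns beyond the pivoted rank if deficient
    _, R, piv = _qr_pivot(Xc)
    diag = np.abs(np.diag(R))
    tol = max(Xc.shape) * np.finfo(float).eps * (diag.max() if diag.size else 0.0)
    rank = int((diag > tol).sum())
    if rank < data.p:
        offenders = [data.names[j] for j in piv[rank:]]
        raise CoxError(f"rank-deficient design; collinear columns {offenders}")


def _qr_pivot(X):
    from scipy.linalg import qr

    Q, R, piv = qr(X, mode="economic", pivoting=True)
    return Q, R, piv


def fit_cox(
    intervals: pd.DataFrame,
    covariates: Sequence[str],
    ties_method: str = "efron",
    tol: float = 1e-9,
    max_iter: int = 50,
    max_halvings: int = 10,
) -> CoxFit:
    """Maximise the partial likelihood by Newton-Raphson with step-halving.

    Covariates are centered at their event-weighted means internally for
    numerical stability; reported coefficients and covariance are on the
    original scale (the partial likelihood is invariant to the shift).
    Monotone likelihood (a diverging coefficient) is flagged, not truncated.
    """
    if ties_method not in ("efron", "breslow"):
        raise CoxError(f"unknown ties method {ties_method!r}")
    data = _CoxData(intervals, covariates)
    _check_rank(data)
    p = data.p

    beta = np.zeros(p)
    ll_null = data.loglik(beta, ties_method)
    if p == 0:
        return CoxFit(
            names=[],
            coefficients=beta,
            covariance=np.zeros((0, 0)),
            log_pl=ll_null,
            log_pl_null=ll_null,
            k=0,
            ties_method=ties_method,
            converged=True,
            n_iter=0,
            n_events=data.n_events,
            n_rows=len(data.start),
        )

    ll, grad, info = data.loglik_grad_info(beta, ties_method)
    converged = False
    message = ""
    it = 0
    for it in range(1, max_iter + 1):
        try:
            step = np.linalg.solve(info, grad)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(info, grad, rcond=None)[0]
        t = 1.0
        new_beta = beta + step
        new_ll = data.loglik(new_beta, ties_method)
        halvings = 0
        while not np.isfinite(new_ll) or new_ll < ll - 1e-12:
            halvings += 1
            if halvings > max_halvings:
                break
            t /= 2.0
            new_beta = beta + t * step
            new_ll = data.loglik(new_beta, ties_method)
        if not np.isfinite(new_ll) or new_ll < ll - 1e-12:
            message = "step-halving failed to improve the likelihood"
            break
        beta, prev_ll = new_beta, ll
        ll, grad, info = data.loglik_grad_info(beta, ties_method)
        if np.any(np.abs(beta) > MONOTONE_BETA) and np.linalg.norm(grad) > 1e-3:
            j = int(np.argmax(np.abs(beta)))
            message = (
                f"monotone likelihood suspected: coefficient {data.names[j]!r} "
                f"diverging (|beta| > {MONOTONE_BETA:g})"
            )
            break
        if abs(ll - prev_ll) < tol * (abs(prev_ll) + 1e-10):
            converged = True
            break
    else:
        message = f"no convergence in {max_iter} iterations"

    if not converged and np.any(np.abs(beta) > MONOTONE_BETA):
        j = int(np.argmax(np.abs(beta)))
        message = (
            f"monotone likelihood suspected: coefficient {data.names[j]!r} "
            f"diverging (|beta| > {MONOTONE_BETA:g})"
        )

    try:
        cov = np.linalg.inv(info)
    except np.linalg.LinAlgError:
        cov = np.full((p, p), np.nan)
    if not converged:
        warnings.warn(f"Cox fit did not converge: {message}", RuntimeWarning)
    return CoxFit(
        names=data.names,
        coefficients=beta,
        covariance=cov,
        log_pl=ll,
        log_pl_null=ll_null,
        k=p,
        ties_method=ties_method,
        converged=converged,
        n_iter=it,
        n_events=data.n_events,
        n_rows=len(data.start),
        message=message,
    )


def breslow_baseline(fit: CoxFit, intervals: pd.DataFrame) -> BaselineHazard:
    """Breslow jumps dLambda0(t_k) = (events at t_k) / sum_{risk} exp(x'beta).

    At beta = 0 this reduces to the Nelson-Aalen estimator.
    """
    data = _CoxData(intervals, fit.names)
    _, w = data._weights(fit.coefficients, center=False)
    S0 = data._range_sum(w)
    increments = data.m / S0
    return BaselineHazard(event_times=data.event_times, increments=increments)


def lr_test(fit_full: CoxFit, fit_nested: CoxFit) -> tuple[float, int, float]:
    """Likelihood-ratio test of a nested Cox model against the full one."""
    if not set(fit_nested.names) <= set(fit_full.names):
        raise CoxError("models are not nested (covariate sets)")
    stat = 2.0 * (fit_full.log_pl - fit_nested.log_pl)
    if stat < -1e-6:
        raise CoxError(
            f"full model has lower log partial likelihood ({fit_full.log_pl:.6f} "
            f"< {fit_nested.log_pl:.6f}); likelihood not maximised"
        )
    stat = max(stat, 0.0)
    df = fit_full.k - fit_nested.k
    p = 1.0 if df == 0 else float(stats.chi2.sf(stat, df))
    return stat, df, p


def backward_eliminate(
    intervals: pd.DataFrame,
    candidate_covariates: Sequence[str],
    alpha: float = 0.01,
    forced_covariates: Sequence[str] = (),
    **fit_kwargs,
) -> tuple[list[str], CoxFit]:
    """Backward elimination by likelihood-ratio tests at level ``alpha``.

    Repeatedly drops the candidate whose single-term LR p-value is largest
    and exceeds ``alpha``; ``forced_covariates`` always stay in the model.
    Returns the retained candidates and the final fit (which includes the
    forced covariates).
    """
    if not 0 < alpha <= 1:
        raise CoxError("alpha must be in (0, 1]")
    retained = list(candidate_covariates)
    forced = list(forced_covariates)
    fit = fit_cox(intervals, forced + retained, **fit_kwargs)
    while retained:
        pvals = {}
        for c in retained:
            reduced = fit_cox(
                intervals, forced + [r for r in retained if r != c], **fit_kwargs
            )
            _, _, pv = lr_test(fit, reduced)
            pvals[c] = pv
        worst = max(pvals, key=pvals.get)
        if pvals[worst] <= alpha:
            break
        retained.remove(worst)
        fit = fit_cox(intervals, forced + retained, **fit_kwargs)
    return retained, fit
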