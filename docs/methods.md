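# Methods

## The illness-death model and its two estimation approaches

The package models a three-state process — initial state 1, transient
intermediate state 2 entered at time *d*, absorbing state 3 entered at
time *t* — with no recovery transition and at most one intermediate event
per subject.  Time is measured in years since diagnosis/entry; month-based
conventions are converted at 1 month = 1/12 year.  The intermediate-event
time is a first-class missing value when the event never occurred; 0 is a
legal event time and is never used as a sentinel.

All fitting is Cox partial likelihood on half-open at-risk intervals
(start, stop]: a subject is at risk at time u iff start < u ≤ stop.  This
one convention carries time-varying covariates (several rows per subject)
and left truncation (delayed entry at *d* for the 2→3 model) without
special-casing, and it makes the instant of the 1→2 transition itself
excluded from the subject's 2→3 risk exposure.

**Approach J** fits one model for both paths into state 3,

λ(t) = λ₀(t)·exp(βᵀ1{t≥d}f(d, t−d) + γᵀz),

so the fixed covariates are constrained to act equally on 1→3 and 2→3 and
the entire effect of the intermediate event is the relation
c(d, s) = exp(βᵀf(d, s)), s = t − d.  The relation family J.I ⊂ J.II ⊂
J.III.{1,2} ⊂ J.IV is nested (term sets ∅, {1}, {1, d} or {1, e^−s},
{1, d, e^−s}), so log-likelihoods are monotone along the chains and AIC
comparison within the family is meaningful.  The 1→2 transition is fitted
separately with its own γ₁₂; nothing downstream consumes it, but it is
reported because the three fits together describe the whole process.

**Approach S** fits each transition separately (own baseline, own γ).
The 2→3 model can run on the forward clock (time since diagnosis, left
truncation at *d*) or the reset clock (time since the intermediate event).
The post/pre hazard ratio λ₂₃(d+s, d)/λ₁₃(d+s) is formed from the two
smoothed baseline hazards times the fitted covariate terms at an explicit
reference covariate pattern (default: all covariates zero, i.e. the
baseline category).  The surface is only defined on the forward clock —
on the reset clock numerator and denominator live on different time axes
— and is masked (NaN), never extrapolated, where d + s leaves the interior
support of either baseline.

AIC comparison **across** the two approaches is refused by
`compare_models`: J conditions both absorbing-state paths on one risk set
while S factorises the likelihood per transition, so their partial
likelihoods are not on a common scale.

## Data-preparation conventions

Two cleaning rules resolve coincident event times before restructuring:
an intermediate event recorded exactly at death is moved one month
earlier, and one recorded simultaneously with distant disease is redrawn
uniformly over the three months preceding it (seeded, reproducible).
Endpoint conventions: for overall survival, subjects with distant disease
but no intermediate event are censored at the distant-disease time — the
source convention states only *that* they are censored, not when; censoring
at the distant-disease time is the package's choice, since from that moment
the subject is no longer at risk inside the modelled three-state scheme.
For distant-disease-free survival the terminal event is the earlier of
distant disease and death.

A subject whose intermediate event coincides with exit is kept as making
1→2 with zero post-event exposure; `drop_simultaneous=True` drops such
subjects instead.

## Counting-process layout and covariate evaluation

Continuously time-varying terms (e^−s and FP bases of s) are evaluated at
each interval's stop, with intervals cut at every observed event time
inside the window where such a term is active, because the partial
likelihood interrogates covariates only at event times.  Rows on which all
terms are step-constant (pre-event rows; any row when the design holds
only the indicator, the linear d term or FPs of d) are left uncut: the
partial likelihood is exactly invariant to refining them, which the test
suite verifies, and the saved rows make large simulation studies cheap.
Passing an explicit `split_times` grid forces the full partition of every
subject.

## Numerics of the Cox engine

Newton-Raphson with step-halving (up to 10 halvings), convergence when the
relative log-likelihood change falls below 1e−9, at most 50 iterations.
Covariates are centered at their event-weighted means internally (the
partial likelihood, its gradient and Hessian are invariant to the shift;
only the exponential sums are stabilised) and results are reported on the
original scale.  Ties: Efron by default, Breslow selectable; the two agree
exactly when no two events share a time.  Risk-set sums are accumulated
with difference arrays over the sorted event times (each interval covers a
contiguous index range), so one evaluation is O(rows·p²) independent of
the number of events.  Monotone likelihood is detected — |β̂| exceeding 20
while the fit has not converged — and flagged with the offending
coefficient's name, never silently truncated.  Rank-deficient designs are
rejected with the collinear columns named (QR with pivoting).  The
covariance is the inverse observed information at the optimum; the Breslow
baseline jumps are (events at t)/Σ_risk exp(xβ̂), reducing to Nelson-Aalen
at β = 0.

## Fractional polynomials

Powers come from S = {−2, −1, −0.5, 0, 0.5, 1, 2, 3}, X⁰ ≡ log X, repeated
powers multiply the second basis term by log X; two-term candidates are
unordered, giving 8 + 36 candidates.  Bases are evaluated only on
post-event intervals and are exactly zero before the event.  A one-day
origin shift (ε = 1/365 year) is applied inside logs and non-positive
powers so near-zero sojourn times do not blow up; positive powers use the
unshifted argument.  No Royston-Altman pre-scaling of X is applied — times
in years are O(1) — though the shift is configurable.  Selection is by AIC
over the null model (term omitted), the straight line (identical to FP1
p = 1), and all FP1/FP2 candidates; non-converging candidates are recorded
and excluded from the arg-min; ties break toward fewer terms, then
lexicographically smaller powers, for determinism.  With several
time-varying covariates, selection cycles conditionally (re-selecting each
variable's transform with the others held at their current best) until a
full cycle changes nothing.

## Baseline smoothing

Cumulative baseline hazards are smoothed with a cubic smoothing spline and
differentiated on an equispaced grid spanning the central 90% of event
times; negative derivative values are clamped to a small positive floor
with a warning.  The penalty defaults to a fixed λ = 1.0 rather than
generalised cross-validation: the increments of a cumulative hazard
estimate are martingale increments, and their serial dependence makes GCV
undersmooth drastically (verified on constant-hazard simulations, where
GCV-selected derivatives wander over half an order of magnitude while
λ = 1 stays within ±25% of the truth).  GCV remains available via
`lam=None`.

## The simulator

`simulate_cohort` draws, per subject, covariates (default: one standard
normal, one balanced binary), latent 1→2 and 1→3 times by closed-form
cumulative-hazard inversion (constant or Weibull baselines, proportional
covariate effects), and — for subjects reaching state 2 — the 2→3 time
from λ₀,₂₃(t)·c(d, t−d)·exp(γᵀz) by numerical inversion of the integrated
hazard (trapezoidal tabulation at 1/500-year resolution up to 10× the
horizon; closed form when the multiplier is absent and the baseline
constant).  A target unreachable by 10× the horizon censors at the
horizon.  Censoring is administrative at the horizon plus optional
exponential censoring.  Random streams are split per subject from the
master seed (`SeedSequence.spawn`), so cohorts are byte-identical across
runs and robust to reordering; the truth record (config, seed, per-subject
latent times) is always produced alongside the cohort.

Default conditions mirror a breast-cancer-like cohort qualitatively: a
5-year horizon, constant baselines λ₁₂ = 0.035, λ₁₃ = λ₂₃ = 0.06 /year and
exponential censoring at rate 0.02, giving roughly 13% intermediate-event
incidence.  What the simulator does **not** emulate: interval-censored
detection of the intermediate event (visit schedules), covariate-dependent
censoring, recurrent intermediate events, or calendar-time effects.
Passing tests therefore demonstrate correctness of the estimators under
exactly observed transition times, not robustness to the screening-induced
biases real registry data may carry.

## Simulation-study designs used in validation

Problem sizes were chosen so each study completes in a few minutes on one
core while leaving Monte-Carlo error well below the margins tested.

* **Exponential-decay recovery** — cohorts of n = 2000 under
  c = exp(1.0 − 0.3·d + 1.5·e^−s) with prognostic covariates
  (γ = (0.4, −0.3)); 100 replications; each coefficient should fall within
  3 standard errors of its generating value in ≥95% of replications.
* **FP power recovery** — cohorts of n = 2000 with λ₁₂ = 0.15, λ₂₃ = 0.30
  and c = exp(−1.0·(s + ε)⁻¹); the best FP1 power should be −1 in the
  majority of 100 replications.  The multiplier's sign matters
  generatively: with a *positive* coefficient on s⁻¹ the 2→3 hazard
  explodes as s → 0 and its integral is astronomically large, so every
  sojourn collapses to zero and the design is degenerate; a negative
  coefficient (risk suppressed immediately after the event, rising to a
  plateau) keeps the process well defined while exercising the same basis.
* **Wald-test size** — cohorts of n = 400 with shared constant baselines
  and c ≡ 1; the nominal-5% Wald test of the constant-relation coefficient
  should reject in 2–8% of 500 replications.
* **Null surfaces** — one cohort of n = 3000 with shared constant
  baselines and c ≡ 1; the J relation surface and the S smoothed-baseline
  ratio should both sit near 1.  The S surface inherits smoothing noise
  from two differentiated baselines; its tolerance band (mean |log ratio|
  below 0.35, and below 0.5 in the broader unit test) was measured on
  independent development seeds and includes a safety margin.

## Known limitations

* The Efron/Breslow engine has no exact-ties likelihood, no penalised or
  stratified fitting, and no frailty terms.
* Transition probabilities (Aalen-Johansen-type functionals) are out of
  scope: with hazards depending on d and t − d the process is not Markov
  and such functionals need different machinery.
* The hazard-ratio surface of approach S is undefined for reset-clock
  fits, and its accuracy near the edges of the event-time support is
  limited by the spline derivative.
* The FP selection uses AIC throughout; the closed-test function-selection
  procedure used elsewhere in the FP literature is not implemented.
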