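# ildcox

Illness-death multi-state Cox models with sojourn-time-dependent
covariates, fractional-polynomial selection of their functional form, and
hazard-ratio surfaces — for studying how an intermediate clinical event
(the motivating case is a first isolated locoregional recurrence of breast
cancer) changes the hazard of a terminal event.

## The problem and the models

A cohort is followed from diagnosis (state 1).  Subjects may experience an
intermediate event at time *d* (state 2) before the absorbing event —
death, or "distant metastases or death" — at time *t* (state 3).  Three
transition hazards describe the process: λ₁₂(t), λ₁₃(t) and λ₂₃(t, d).
The scientific question is how λ₂₃ relates to λ₁₃: does the intermediate
event change the risk at all, and does the change depend on the waiting
time *d* and/or the sojourn time *t − d*?

Two estimation strategies are provided, both Cox models on start-stop
(counting-process) data:

* **Approach J (joint).**  Transitions 1→3 and 2→3 share one baseline
  hazard and common covariate effects γ; the change after the intermediate
  event enters through time-varying covariates gated by the indicator
  1{t ≥ d}:

      λ(t) = λ₀(t) · exp( βᵀ 1{t ≥ d} f(d, t − d) + γᵀ z ).

  The hazard ratio is then the parametric relation
  c(d, t − d) = exp(βᵀ f(d, t − d)), with a nested family of shapes:
  c ≡ 1 (J.I), constant (J.II), a function of d (J.III.1), of t − d
  (J.III.2), of both (J.IV, canonically exp(β₀ + β₁d + β₂e^−(t−d))), or a
  fractional polynomial of t − d (J.FP).  Nesting makes AIC comparison
  across the family direct.

* **Approach S (separate).**  Each transition gets its own Cox model and
  baseline; the 2→3 model is left-truncated at *d* on the "clock forward"
  scale (time since diagnosis) or shifted to the "clock reset" scale (time
  since the event).  The post/pre hazard ratio λ₂₃/λ₁₃ then involves the
  two baselines, estimated by smoothing the Breslow cumulative hazards and
  differentiating.

Functional forms for the time-varying covariates are selected with
fractional polynomials: powers from S = {−2, −1, −0.5, 0, 0.5, 1, 2, 3}
(X⁰ ≡ log X; a repeated power adds an X^p·log X term), giving 8 one-term
and 36 two-term candidates ranked by AIC.

Because no suitable cohort is publicly deposited, the package ships a
full illness-death simulator (`ildcox.simulate`) with proportional-hazards
covariate effects, sojourn-time-dependent 2→3 multipliers, and
administrative plus random censoring; every estimator is validated against
it.

## Worked example

```python
import ildcox as ic
from ildcox.simulate import SimConfig, CSpec, simulate_cohort

cfg = SimConfig(
    n=2000, seed=3,
    c_spec=CSpec("exp_decay", b0=1.0, b1=-0.3, b2=1.5),
    gamma12=(0.2, 0.0), gamma13=(0.4, -0.3), gamma23=(0.4, -0.3),
)
cohort, truth = simulate_cohort(cfg)

res = ic.fit_joint(cohort, relation="J.IV")
print(res.summary())
```

prints

```
Joint illness-death model  (relation J.IV, endpoint overall_survival)
rows 52672, events 517, log PL -3718.5540, AIC 7447.11, converged True (5 it)

Shared 1->3 / 2->3 hazard:
                   coef  exp(coef)     se       z      p
in_state_2       1.5426     4.6768 0.2010  7.6755 0.0000
onset_time      -0.4354     0.6470 0.0993 -4.3849 0.0000
exp_neg_sojourn  0.9550     2.5987 0.3487  2.7390 0.0062
z_cont           0.3655     1.4413 0.0455  8.0392 0.0000
z_bin           -0.4270     0.6525 0.0894 -4.7791 0.0000

Transition 1->2:
          coef  exp(coef)     se       z      p
z_cont  0.3055     1.3573 0.0601  5.0834 0.0000
z_bin  -0.2949     0.7446 0.1196 -2.4658 0.0137
```

`in_state_2`, `onset_time` and `exp_neg_sojourn` estimate β₀, β₁ and β₂ of
the relation c(d, t−d) = exp(β₀ + β₁d + β₂e^−(t−d)); each is within three
standard errors of the generating values (1.0, −0.3, 1.5).  The hazard
quadruples right after an early intermediate event (c ≈ exp(1.54 + 0.96) at
d ≈ 0, s ≈ 0) and relaxes toward exp(β₀ + β₁d) as the sojourn grows.
`res.c_surface()` evaluates the fitted relation on a (d, s) grid;
`ic.compare_models([...])` ranks the J.I–J.IV family by AIC;
`ic.select_fp(...)` sweeps the 8 + 36 FP candidates for the sojourn term;
`ic.fit_separate(cohort).hazard_ratio_surface()` gives the
smoothed-baseline ratio of approach S.

A command-line interface mirrors the library:

```bash
ildcox simulate --seed 7 --n 1000 -o cohort.csv
ildcox fit cohort.csv --approach J --relation J.IV -o fit.json
ildcox compare cohort.csv -o aic.csv
ildcox fpselect cohort.csv --variable sojourn -o fp.json
```

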