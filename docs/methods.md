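# Methods

## Model structure

The cohort model tracks occupancy over six mutually exclusive states: four
alive states defined by KCCQ-TSS quartile bands (lower-closed cut points at
50, 69.8 and 87.5; a score of exactly 50 belongs to Q2, and 100 to Q4) and
two absorbing death states (CV, non-CV). Cut points are held fixed over the
horizon. The cycle length is 28 days and the horizon 28 years — 366 cycles
from a default start age of 72, by which point occupancy of the alive
states is negligible. Within a cycle, deaths are applied first to every
alive state (the per-cycle CV and non-CV probabilities are taken as given
rather than hazard-partitioned; the ordering is a modelling choice, made
explicit here because cycle probabilities are small enough that the
alternatives agree to well below reporting precision), and survivors then
redistribute among the KCCQ states by the transition matrix.

Start occupancy defaults to (23.95, 26.15, 24.55, 25.35)% across Q1–Q4,
the baseline quartile distribution of a contemporary HFmr/pEF trial
population; the cohort is a fixed 54.5/45.5 male/female mixture for
life-table lookups (no remixing as differential mortality accrues — a
simplification, since the model does not track sex-specific occupancy).

## Mortality

CV and all-cause death are modelled as parametric survival curves on the
year scale. Six families are fitted by maximum likelihood (exponential,
Weibull, log-normal, log-logistic, Gompertz, generalised gamma) and
compared on AIC (or BIC); ties within 2 units resolve to the family with
fewer parameters. The Gompertz family is implemented as a custom lifelines
fitter restricted to the increasing-hazard branch (both parameters
positive), which is the relevant regime for mortality in an elderly HF
cohort. Curves are fitted per arm; a proportional-hazards treatment effect
is not imposed.

Per-cycle probabilities derive from conditional survival,
`p(t) = 1 − S(t+Δ)/S(t)`. Non-CV death is the all-cause minus CV
remainder, floored at zero, and capped each cycle by the CV-deleted
life-table probability `qx·(1 − cv_fraction)` at the integer attained age
(floor of start age plus elapsed years), converted to the cycle length
under a constant hazard within the year. The cap prevents extrapolated
trial mortality from falling below general-population mortality;
CV-deletion avoids double counting CV deaths, which the trial-based curve
already captures. The packaged life table is a synthetic Gompertz–Makeham
table (male q70 ≈ 0.020, female ≈ 0.011, constant CV fraction 0.27,
terminal age 110 with qx = 1) standing in for a national table; real
tables load from CSV with columns `age, sex, qx, cv_fraction`.

## Recurrent HF events

Expected HHF and UHFV counts per cycle come from log-linear rate models
fitted by GEE on a subject × cycle panel: Poisson family, log link,
exchangeable working correlation within subject, and a log-exposure offset
so coefficients refer to a full 28-day cycle. Covariates are attained age
(continuous, years), male sex, and race contrasts against White; a level
absent from the data is dropped with a warning. The exchangeable
correlation is the standard choice for recurrent counts; an independence
option exists, under which the intercept-only fit satisfies the exact
score identity (predicted mean = observed mean count per unit exposure) —
under exchangeable weighting with unequal cluster sizes the identity holds
only approximately.

In the engine the cohort-expected rate averages the log-linear predictor
over the sex × race mixture at the current attained age, multiplied by the
half-cycle-corrected alive mass. Because age enters continuously, the
modelled per-cycle rate rises as the cohort ages — the mechanism behind
the model's strong sensitivity of cumulative HHF counts to baseline age,
and a recognised source of overestimation relative to a trial population
with dispersed ages (a cohort model carries the whole cohort at the mean
age, and the exponential link makes the rate convex in age).

## Rate and proportion conversions

Published constant rates convert to per-cycle probabilities by the
constant-hazard transform `p = 1 − exp(−(rate/100)·Δyears)`; a month is
1/12 year, so 3.56 events per 100 person-years gives a monthly probability
of 0.0030 (4 dp). Observed adverse-event proportions convert by
`p = 1 − (1 − proportion)^(Δ/followup)`, which compounds back to the
observed proportion over the follow-up — both assume constant risk over
time. At these magnitudes the exponential transform and naive division are
indistinguishable at printed precision; the exponential form is used
throughout for internal consistency.

## Utilities and accounting

State utilities default to (0.64, 0.74, 0.81, 0.87) for Q1–Q4 — values in
the range reported for KCCQ-quartile states in recent HF utility studies,
ordered so that better symptom status carries higher utility. Utility
falls with attained age by −0.0051 per year. HHF/UHFV disutilities (0.042,
0.015) and small per-occurrence AE disutilities apply as one-off QALY
decrements per expected event, with no duration convention — the usual
treatment of recurrent-event disutilities in KCCQ-state HF models.
Adverse events enter as constant per-cycle probabilities (configurable
basket; hyperkalaemia is the clinically salient entry for a
mineralocorticoid-receptor antagonist).

LY and QALY accrue trapezoidally (half-cycle correction on the alive mass
and on the utility-weighted occupancy); cumulative event counts reported
for validation use the same mid-cycle convention. Discounting is
continuous-exponent, `(1+d)^(−t_years)` at cycle start, from time zero, at
3.5%/year by default. A first-year-exempt dialect
(`(1+d)^(−max(t−1,0))`) is provided because comparator models differ in
whether year one is discounted; the comparator-adjusted scenario uses it.
Neither convention is claimed as ground truth.

## Treatment discontinuation

Time to all-cause discontinuation of the active therapy is fitted with the
same six-family machinery (the synthetic generator draws it log-normal,
median 28 months, σ = 1.1 on the log scale, and the log-normal family is
recovered by AIC). The active-arm run blends active and control per-cycle
risk sets (mortality, event rates, transitions, AEs) by the on-treatment
fraction S_disc(t): patients who stop therapy carry control-arm risks
thereafter, matching the assumption that they continue on SoC.

## Scenario adapters

The comparator-adjusted scenario switches to 1-month cycles, constant
per-cycle mortality/event/discontinuation probabilities (all required
caller inputs — they are the comparator's own values and are deliberately
not defaulted), a 3% discount rate, no AE disutilities, HF-event
disutilities only for cycles starting after 365.25 days, and first-year
discount exemption. All-cause mortality remains life-table capped. The
external-validation scenario zeroes discontinuation (necessary for an
on-treatment comparison; provably a no-op for the control arm), sets a
29-month undiscounted horizon, and sets the start age. 29 months is 31.5
cycles of the 28-day grid; the engine runs 32 cycles and linearly
interpolates cumulative counts to the window end.

## Validation statistics

Absolute difference is |trial − model|; relative difference is
100·absolute/|trial|. The incremental contrast uses active − control on
both sides and |trial incremental| as the denominator — this choice
reproduces every printed difference cell of the published table.
Published tables may print an incremental row computed before the arm
counts were rounded (the arm counts then no longer difference to the
printed incremental); the report generator therefore accepts explicit
incremental counts as inputs and otherwise differences the arms.
Rounding (half-up, counts to integers, percents to 1 dp) applies only at
presentation.

## Sensitivity analysis

DSA varies one parameter at a time between deterministic bounds, others at
base, and sorts by outcome range. PSA re-draws all parameters each
iteration (default 1000) from prespecified families — beta for
probabilities and utilities, gamma/log-normal for rates, Dirichlet for
transition-matrix rows, normal for unconstrained log-rate coefficients —
addressed by dotted paths into the spec/inputs pair. Each iteration uses
an independent substream spawned from the master seed, so results are
independent of evaluation order; intervals are 2.5/97.5 percentiles.
Survival curves are evaluated in closed form from their stored parameters
(the generalised gamma falls back to the fitted object), so perturbing a
fitted parameter propagates to the curve.

## Synthetic trial generator

The generator emulates the structure the model assumes, under default
"study conditions" chosen once: baseline age truncated-normal(72, 10) on
[40, 97]; 54.5% male; race mix 78/15/2/5% White/Asian/Black/Other; KCCQ
baseline quartile occupancy (23.95, 26.15, 24.55, 25.35)% with scores
uniform within band; recurrent events from the same log-linear per-cycle
models the engine uses (control HHF 10.5 and UHFV 1.85 per 100
person-years at the reference mix, rate ratios ≈0.70/0.54 under
treatment, age coefficient +0.025/yr for HHF), evaluated
piecewise-constant on the 28-day grid so generator and engine share a
clock; exponential cause-specific mortality (CV 2.7 vs 2.3 per 100
person-years control/active, non-CV 1.6 in both) with first-event-wins
competing risks; log-normal discontinuation (active arm only); KCCQ
assessments every 30 days evolving by a monthly quartile matrix; censoring
at 29 months. These magnitudes make a ~3000-per-arm trial produce event
counts of the order seen in recent phase 3 HFmr/pEF trials. Arm sizes are
a required input wherever counts are scaled to a trial (3003/2998 is used
in the examples).

What the generator does **not** emulate: correlation between KCCQ
trajectory and event/mortality risk (states and events are conditionally
independent given covariates), non-proportional or time-varying treatment
effects, seasonal or enrollment-time structure, and measurement error in
KCCQ beyond band-uniform scores. Passing tests therefore demonstrate
correctness of estimation and accounting under the assumed structure, not
fidelity to any particular real dataset.

## Numerical choices and degenerate inputs

- Mass conservation is enforced to 1e-9 per cycle and observed at ~1e-13
  over 366 cycles; transition rows must sum to 1 within 1e-9.
- A single-subject exponential fit uses the closed-form MLE (optimiser
  backends need ≥2 rows); all-censored data raise an estimation error.
- An event type with zero observed events yields a flagged zero-rate model
  rather than a −∞ intercept.
- A KCCQ quartile never observed as an origin keeps an identity transition
  row, with a warning.
- The microsimulation oracle mirrors the engine's half-cycle conventions:
  a subject dying within a cycle contributes half a cycle of alive time
  and half a cycle of event exposure.
- Seeds: the generator is byte-reproducible for a fixed seed; PSA spawns
  one substream per iteration from the master seed.

## Problem sizes

Default analysis sizes: 3000 subjects per arm for estimation recovery,
100,000 subjects for the microsimulation cross-check, 1000 PSA
iterations. The test suite uses an 800-per-arm trial for fitted fixtures
and 25,000–50,000 draws for moment-recovery checks.

## Known limitations

- Costs, ICERs and net monetary benefit are out of scope; the model
  reports clinical outcomes (LY, QALY, event counts) only.
- The NYHA-class alternative state structure is not implemented.
- Renal outcomes beyond a generic adverse-event channel are not modelled.
- Sex-specific occupancy is not tracked (fixed mixture for life-table
  lookups).
- The Gompertz family is restricted to increasing hazards.
- Exact external-validation age-invariance of CV deaths holds only when
  the life-table cap is disabled, since the cap itself depends on
  attained age.
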