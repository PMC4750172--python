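# Methods

## Model structure and assumptions

The engine is a deterministic cohort model in discrete time: expected
state occupancy for a closed cohort, one-hour cycles, states
`pre_active → active_stage1 → active_stage2 → {delivered_vaginal,
delivered_caesarean} → inpatient → discharged`. Delivery is governed by
per-stratum cumulative-incidence curves indexed by time since induction
(cycle 0 = insert placement); everything else (the oxytocin split, the
care schedule) is constant over time.

Rather than stepping a transition matrix, the implementation schedules
labour-state residency *backwards* from each delivery-time atom: a woman
delivering during cycle `t` spends cycle `t` in the second stage (capped
at one hour, consistent with intrapartum guidance that second-stage
observations are hourly), up to four preceding cycles in the first
stage, and the remainder in pre-active labour. This is algebraically a
Markov model on an extended state space and has two advantages: the
calibrated delivery-time distribution is preserved exactly (the trace's
cumulative `delivered_vaginal` column at cycle `c` is `n·F_vd(c)` by
construction), and per-state occupancy is still available for the
resource model. Mass is conserved to 1e−9 at every cycle across the
exclusive states; the delivery counters are cumulative and monotone.

Caesareans are a competing outcome. No caesarean timing is published,
so the time-to-caesarean curve defaults to the vaginal-delivery curve's
shape rescaled to the caesarean mass (i.e. identical conditional timing).
This assumption is echoed in the report's assumptions appendix; it makes
the all-deliveries distribution equal the conditional vaginal-delivery
distribution, which is the most neutral choice available.

All duration summaries use the mid-cycle convention (an event during
cycle `t` is timed at `t + 0.5` h), the standard half-cycle correction
for discrete-time cohort models.

**Prolonged labour** is reported as the share of the induced cohort
without a vaginal delivery within 24 h — caesareans count as prolonged.
This matches the framing "one third … deliver vaginally within 24 h,
with the remainder experiencing prolonged onset and duration of labour";
conditioning on vaginal delivery instead would give materially smaller
numbers.

**Per-induction hours.** Cohort totals of time-to-vaginal-delivery use
the per-induction convention: mean hours among women delivering
vaginally × number of inductions. This is the convention under which
the published total (hours saved per year) divides back exactly to the
published per-induction saving.

## Calibration

Inputs per stratum (arm × parity): the 12-h and 24-h vaginal-delivery
proportions; per arm: the overall caesarean rate (terminal mass
= 1 − caesarean rate) and the mean time to vaginal delivery.

The proportions are interpreted as cumulative incidence in the presence
of the competing caesarean — they are proportions of *all* randomised
women, not of vaginal deliveries.

Families:

* **weibull / log_logistic** — two parameters, exactly identified by the
  two anchors. Solved by bisection on the shape over [0.05, 20] (the
  scale is closed-form from the first anchor at each iterate), bracket
  width tolerance 1e−10, with an explicit 1e−8 post-check of both
  anchors. Deterministic; no seed involved.
* **piecewise_exponential** (base-case default) — constant hazards on
  [0, 12), [12, 24), [24, ∞). The first two rates are closed-form from
  the anchors. The tail rate is unidentified by the anchors; by default
  it continues the second-segment rate, but the base case solves a
  single per-arm multiplier on the stratum tail rates (Brent's method on
  a monotone function) so that the parity-weighted mean among delivered
  equals the published arm-level mean (25.2 h DVI / 18.2 h MVI).

The tail calibration is the reason the default family is not a
two-parameter curve: a Weibull through the anchors implies arm means of
26.7 h (DVI) and 20.6 h (MVI), i.e. it ignores two published inputs and
inflates both tails; with the anchors + mean calibration the model
reproduces the published time-saved, bed-hour and capacity figures
without touching any other parameter. Two-parameter families remain one
config switch away (`calibration.family`) for tail-sensitivity checks;
all families agree exactly at the anchor times by construction.

The published medians (32.8/21.5 h) are carried as reference values
only: they are trial-level summaries under the trial's parity mix,
which is not published, so they cannot be used as stratum constraints.

## Key parameters, defaults, and why

| parameter | default | basis |
|---|---|---|
| cohort | 1397 inductions; 741 parous / 656 nulliparous; 6140 births/yr | published hospital year |
| anchors (12/24 h) | DVI parous .183/.543, DVI nulli .016/.131, MVI parous .356/.700, MVI nulli .059/.271 | published |
| caesarean rate | .271 DVI / .260 MVI | published |
| mean time to VD | 25.2 h DVI / 18.2 h MVI | published (tail-calibration target) |
| oxytocin probability | .741 DVI | trial rate ("three quarters") |
| | .464 MVI | back-calculated from the published oxytocin set-up workload (27 vs 43 shifts at 8-h shifts); only "fewer women" is stated directly. Reproduces 27/43 after rounding |
| oxytocin duration | 14 h DVI / 11 h MVI | published; carried in profiles and synthetic records, not a workload driver (no published monitoring parameter attaches to it) |
| active labour | 4 h first stage + 1 h second stage | care-schedule footnote (second stage ≤ 1 h); configurable |
| care schedule | VE 10 min (once pre-active; q4h active, q3h with oxytocin); VSM 3 min (q4h pre-active/stage 1, hourly stage 2); set-up 2 × 10 min | published table |
| shift length | 8 h | not published; the value that reconciles the published oxytocin set-up shift counts with the set-up task and oxytocin rates |
| inpatient stay | 6 h | minimum postnatal observation before discharge after uncomplicated vaginal birth; identical across arms, so it never affects savings, only the per-induction bed footprint |
| horizon | 168 cycles | leaves < 0.01 % of every stratum undelivered (120 cycles leaves 0.15 % of DVI-nulliparous women undelivered under the calibrated tail) |
| residual-mass threshold | 0.1 % | run aborts with an error beyond it |

Scheduled care events use the **completed-interval convention**: an
event fires at each whole multiple of the interval elapsed within a
state, and the single pre-active examination fires at state entry. This
is deterministic and is verified in the tests against brute-force
hour-by-hour enumeration; alternative conventions differ by at most one
event per state and are inside the ±50 % sensitivity envelope.

**Bed occupancy and capacity.** Labour-suite occupancy runs from
induction to delivery (the published bed savings are attributed to the
labour and delivery suite); the postnatal stay is excluded from the
savings (it is identical across arms) but included in the per-induction
bed footprint that divides the saved hours into additional inductions —
an extra induction occupies a bed from insertion to discharge. The
births-per-midwife ratio is adjusted multiplicatively by the fractional
occupancy reduction, the only formula consistent with the published
33.0 → 24.0 movement under a 27.4 % reduction.

**Adverse events** are expected counts: published per-arm rates × 1397,
rounded half-up. The total uses the published total-AE rate (the
categories do not sum to it); the headline fold change is computed from
the rounded counts, with the rate-based fold reported alongside.

## Sensitivity analysis

Schedule parameters (examination duration, observation duration, set-up
duration, examination frequency) are perturbed by factors {0.5, 1.5},
one-way plus the all-durations and all-parameters corners, with the
clinical traces held fixed (only care-process parameters vary).
Frequency perturbation scales the examination *interval* (0.5 = twice as
often). The grid always contains the base case, which is bit-identical
to a standalone run. The continuous-monitoring scenario applies the
with-oxytocin examination interval to every MVI woman; set-up remains
limited to actual oxytocin recipients.

## Synthetic cohorts and validation

`sample_cohort` draws woman-level records from a single seeded
`numpy.random.Generator`: delivery mode from the sub-distribution
masses, delivery time by inverse-CDF from the conditional distribution
(closed-form quantile functions for all three families, no rejection
step — the micro-simulation distribution *is* the calibrated curve), an
independent Bernoulli oxytocin flag. Identical (seed, parameters) give
byte-identical cohorts.

`km_estimate` is the Aalen–Johansen cumulative-incidence estimator
(via `lifelines`) with caesarean as the competing event; with no
censoring it coincides with simple event counting, which the tests use
as an independent cross-check. `microsim_vs_cohort` compares empirical
12/24-h proportions, mean times, bed-hours and workload minutes against
the deterministic trace, using the trace's own discretisation
conventions, and flags any metric outside 3 Monte-Carlo standard errors
(strata under 100 records are marked underpowered instead).

What the synthetic data do *not* emulate: covariate structure, censoring
or withdrawal, oxytocin–delivery-time dependence (the model assumes
independence), time-varying oxytocin need, or any real patient-level
heterogeneity beyond the calibrated marginals. Passing validation shows
the deterministic engine and the sampler implement the same model — not
that the model matches real patient-level data, which remain
unpublished.

## Problem sizes

The deterministic pipeline (calibration, four strata × 168 cycles,
resources, DSA grid) runs in well under a second. Validation uses
100,000 women per stratum, a few seconds in total; the full test suite
runs in a few seconds.

## Known limitations

* The overall midwife-shift saving computed from the published care
  schedule alone is ≈33 shifts/year (20 % of the DVI total), smaller
  than the published 52 (25.2 %). The published per-activity shift
  figures cannot be derived from the published schedule under any shift
  length (e.g. the examination workload attributed to oxytocin
  recipients exceeds what the schedule can generate while their
  observation workload falls below it), indicating the original
  spreadsheet contained workload components beyond the published table —
  its narrative points to oxytocin-duration-driven monitoring, for which
  no parameter is published. We deliberately model only the published
  schedule; the direction, the set-up shift counts (27 vs 43), the
  sensitivity conclusions (saving ≥ 20 shifts in the worst corner) and
  the continuous-monitoring scenario (≈32 vs published 30 shifts) are
  all reproduced.
* Inpatient stay is a single deterministic duration for all women; bed
  differences therefore arise entirely before delivery.
* Caesarean timing shares the vaginal-delivery shape (no published
  anchor); oxytocin status is independent of delivery time.
* The model is deterministic; parameter uncertainty is explored only
  through the ±50 % scenario grid, not probabilistically.
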