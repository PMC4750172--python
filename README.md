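# inductsim

An hourly-cycle Markov cohort model of labour induction at term,
comparing the misoprostol vaginal insert (MVI) with the dinoprostone
vaginal insert (DVI) from a hospital perspective: time to vaginal
delivery, treatment-related adverse events, midwife workload,
labour-suite bed occupancy and ward capacity. It is aimed at
health-economics and maternity-service analysts who want a transparent,
tested, configurable re-implementation of this class of
resource-use model, rather than a spreadsheet.

## The model

A closed cohort of `n` induced women per stratum (treatment arm ×
parity) is propagated through one-hour cycles from insert placement
through **pre-active labour → active labour (first stage, then a
one-hour second stage) → delivery (vaginal or caesarean) → postnatal
inpatient stay → discharge**.

Transitions into the delivery states are time-since-induction indexed.
For each stratum, the cumulative incidence of vaginal delivery
`F_vd(t)` (a sub-distribution that plateaus at `1 − P(caesarean)`) is
calibrated so that `F_vd(12)` and `F_vd(24)` equal the published 12-h
and 24-h vaginal-delivery proportions exactly, and the per-cycle hazard
is

```
p(t) = (F(t+1) − F(t)) / (1 − F(t)),   t = 0, 1, 2, …
```

Because two anchor points say nothing about the tail of the
distribution, the default curve family is a three-segment
piecewise-exponential whose tail rate is solved so the parity-weighted
mean time to vaginal delivery matches the published arm-level mean
(25.2 h DVI, 18.2 h MVI) — both the anchors and the means are published
model inputs. Weibull and log-logistic two-parameter fits are available
as alternatives.

Midwife workload integrates the care schedule (10-min vaginal
examinations: once in pre-active labour, every 4 h in active labour or
every 3 h with oxytocin; 3-min vital-signs observations every 4 h, hourly
in the second stage; a two-midwife 10-min oxytocin set-up) over the
cohort's delivery-time distribution, and converts minutes to 8-h shifts.
A deterministic ±50 % sensitivity analysis perturbs the schedule, and a
scenario applies with-oxytocin monitoring to every MVI woman. A seeded
micro-simulation (inverse-CDF sampling from the calibrated curves)
cross-validates the deterministic trace within Monte-Carlo error.

## Worked example

```python
from inductsim import LabourInductionModel

results = LabourInductionModel.basecase().fit()
print(results.summary())
```

```
Labour induction cohort model: MVI vs DVI
==========================================================
Cohort: 1397 inductions (741 parous / 656 nulliparous), 6140 annual births
Curve family: piecewise_exponential (tail calibrated to printed means: True)

Clinical effectiveness
----------------------------------------------------------
  Mean time to vaginal delivery   DVI   25.2 h   MVI   18.2 h
  Hours to VD saved (cohort/yr)       9772 h (27.8 %)
  Saving per induction                 7.0 h
  VD within 12 h                  DVI  10.5 %   MVI  21.7 %
  VD within 24 h                  DVI  35.0 %   MVI  49.9 %
  Prolonged labour (>24 h)        DVI  65.0 %   MVI  50.1 %

Resource use (per year)
----------------------------------------------------------
  Midwife shifts (8 h)            DVI  160.1     MVI  127.4   saved  32.7 (20.4 %)
  ... oxytocin set-up             DVI   43.1     MVI   27.0
  Suite bed-hours saved               9771 h (407 bed days, 27.7 %)
  Additional inductions/yr             403
  Births per midwife              33.0 -> 23.8

Treatment-related adverse events
----------------------------------------------------------
  Expected events                 DVI     36     MVI    140   (+0.07 per woman, 3.9-fold)
```

Reading it: switching the year's 1397 inductions from the DVI to the
MVI saves about 7 h to vaginal delivery per induction (≈9,800 cohort
hours, a 27.8 % reduction), frees ≈9,800 labour-suite bed-hours
(≈407 bed days, room for ≈400 extra inductions on the same beds), cuts
midwife workload by ≈33 eight-hour shifts per year (oxytocin set-up
falling from 43 to 27 shifts), and is expected to generate 140 rather
than 36 treatment-related adverse events (+0.07 per woman) — the
clinical trade-off the model quantifies.

Downstream analyses hang off the results object:

```python
grid = results.sensitivity()                       # ±50 % schedule DSA
scen = results.scenario_continuous_monitoring()    # MVI continuous monitoring
table = results.validate(n_per_stratum=100_000)    # micro-simulation check
```

or from the shell: `inductsim run`, `inductsim calibrate`,
`inductsim dsa`, `inductsim scenario`, `inductsim simulate`,
`inductsim validate` (see `inductsim --help`).

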