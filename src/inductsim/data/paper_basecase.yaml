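# Base-case configuration: published model inputs for the comparison of
# the misoprostol vaginal insert (MVI) with the dinoprostone vaginal
# insert (DVI) at a UK hospital (one year of inductions).
schema_version: 1

cohort:
  n_total: 1397          # inductions over one year
  parous: 741            # 53.0 %
  nulliparous: 656       # 47.0 %
  annual_births: 6140    # all births that year (22.8 % induced)

arms:
  DVI:
    cs_total: 0.271            # overall caesarean rate
    mean_vd_h: 25.2            # printed mean time to vaginal delivery
    median_vd_h: 32.8          # printed median (reference only)
    oxytocin_prob: 0.741       # "three quarters" of DVI inductions augmented
    oxytocin_duration_h: 14.0  # average administration (reference)
    anchors:
      parous:       {p_vd_12h: 0.183, p_vd_24h: 0.543}
      nulliparous:  {p_vd_12h: 0.016, p_vd_24h: 0.131}
  MVI:
    cs_total: 0.260
    mean_vd_h: 18.2
    median_vd_h: 21.5
    oxytocin_prob: 0.464       # back-calculated from the printed oxytocin
                               # set-up workload (27 vs 43 shifts)
    oxytocin_duration_h: 11.0  # three hours shorter than with the DVI
    anchors:
      parous:       {p_vd_12h: 0.356, p_vd_24h: 0.700}
      nulliparous:  {p_vd_12h: 0.059, p_vd_24h: 0.271}

# treatment-related adverse-event rates (proportion of the cohort)
ae_rates:
  DVI:
    total_ae: 0.026
    tachysystole_no_fhr: 0.006
    tachysystole_fhr: 0.012
    pph: 0.001
    meconium: 0.006
    nicu_admission: 0.001
    low_apgar: 0.000
    uterine_rupture: 0.000
    neonatal_acidosis: 0.000
  MVI:
    total_ae: 0.100
    tachysystole_no_fhr: 0.019
    tachysystole_fhr: 0.060
    pph: 0.000
    meconium: 0.012
    nicu_admission: 0.006
    low_apgar: 0.001
    uterine_rupture: 0.001
    neonatal_acidosis: 0.001

calibration:
  family: piecewise_exponential   # anchors hit exactly; tail calibrated
  calibrate_tail_to_mean: true    # honour the printed arm-level means
  active_labour_first_stage_h: 4.0
  active_labour_second_stage_h: 1.0   # second stage capped at one hour

schedule:                  # observed care pattern
  ve_duration_min: 10.0
  ve_interval_active_h: 4.0
  ve_interval_active_oxytocin_h: 3.0
  vsm_duration_min: 3.0
  vsm_interval_pre_active_h: 4.0
  vsm_interval_stage1_h: 4.0
  vsm_interval_stage2_h: 1.0
  oxytocin_setup_min_per_midwife: 10.0
  oxytocin_setup_midwives: 2

staffing:
  shift_length_h: 8.0               # not printed; reconciles the printed
                                    # oxytocin set-up shift counts
  current_births_per_midwife: 33.0
  recommended_ratio: 29.5

sensitivity:
  parameters: [ve_duration, vsm_duration, oxytocin_setup_duration, ve_frequency]
  factors: [0.5, 1.0, 1.5]

inpatient_stay_h: 6.0    # minimum postnatal observation before discharge
horizon: 168             # hourly cycles; residual undelivered mass < 0.01 %
seed: 12345
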