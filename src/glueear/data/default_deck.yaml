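schema_version: 1
probabilities:
  otorrhoea:
    alpha: 1439
    beta: 4052
    mean: 0.262
    source_ref: 'Table 1, VTs post-operative complications: ear discharge (otorrhoea)'
  granulation:
    alpha: 37
    beta: 850
    mean: 0.042
    source_ref: 'Table 1, VTs post-operative complications: granulation tissue'
  perforation_first:
    alpha: 178
    beta: 7929
    mean: 0.022
    source_ref: 'Table 1, VTs post-operative complications: tympanic membrane perforation,
      1st insertion'
  perforation_subsequent:
    alpha: 557
    beta: 2799
    mean: 0.166
    source_ref: 'Table 1, VTs post-operative complications: tympanic membrane perforation,
      >=2 insertions'
  removal_first:
    alpha: 6
    beta: 77
    mean: 0.072
    source_ref: 'Table 2, VTs care-pathway probabilities: removal of VTs, 1st insertion'
  removal_subsequent:
    alpha: 7
    beta: 34
    mean: 0.171
    source_ref: 'Table 2, VTs care-pathway probabilities: removal of VTs, >=2 insertions'
  reinsertion_2nd:
    alpha: 25
    beta: 75
    mean: 0.25
    source_ref: 'Table 2, VTs care-pathway probabilities: re-insertion of 2nd VTs'
  reinsertion_3rd:
    alpha: 25
    beta: 75
    mean: 0.25
    source_ref: 'Table 2, VTs care-pathway probabilities: re-insertion of 3rd VTs'
costs:
  vt_insertion:
    kind: gamma
    shape: 130.45
    scale: 6.83
    mean: 891
    source_ref: 'Table 4, resource use and unit costs (GBP 2010-11): insertion of
      VTs'
  tympanoplasty:
    kind: gamma
    shape: 100.11
    scale: 18.29
    mean: 1831
    source_ref: 'Table 4, resource use and unit costs (GBP 2010-11): tympanoplasty'
  vt_removal:
    kind: gamma
    shape: 130.45
    scale: 6.83
    mean: 891
    source_ref: 'Table 4, resource use and unit costs (GBP 2010-11): removal of VTs'
  ha_device:
    kind: fixed
    value: 80
    source_ref: 'Table 4, resource use and unit costs (GBP 2010-11): hearing aid (each)'
  ear_mould:
    kind: fixed
    value: 17
    source_ref: 'Table 4, resource use and unit costs (GBP 2010-11): ear-mould (each)'
  ha_maintenance_kit:
    kind: fixed
    value: 20.88
    source_ref: 'Table 4, resource use and unit costs (GBP 2010-11): HA maintenance
      kit'
  ha_battery:
    kind: fixed
    value: 0.49
    source_ref: 'Table 4, resource use and unit costs (GBP 2010-11): HA battery (each)'
  ha_fitting:
    kind: gamma
    shape: 71.03
    scale: 1.07
    mean: 76
    source_ref: 'Table 4, resource use and unit costs (GBP 2010-11): HA fitting (pair)'
  medication:
    kind: fixed
    value: 11
    source_ref: 'Table 4, resource use and unit costs (GBP 2010-11): medication course'
  gp_visit:
    kind: gamma
    shape: 341.67
    scale: 0.12
    mean: 41
    source_ref: 'Table 4, resource use and unit costs (GBP 2010-11): GP visit'
  audiology_visit:
    kind: gamma
    shape: 64
    scale: 0.75
    mean: 48
    source_ref: 'Table 4, resource use and unit costs (GBP 2010-11): audiological
      assessment'
  ent_visit:
    kind: gamma
    shape: 84.14
    scale: 1.09
    mean: 91.72
    source_ref: 'Table 4, resource use and unit costs (GBP 2010-11): ENT outpatient
      visit'
gains:
  gain_vts_year1:
    strategy: VTs
    horizon: year1
    mean_dBHL: 13.06
    sd_dBHL: 9.49
    source_ref: 'Table 3, dBHL gain parameters: VTs after 1 year'
  gain_vts_year2:
    strategy: VTs
    horizon: year2
    mean_dBHL: 12.24
    sd_dBHL: 9.1
    source_ref: 'Table 3, dBHL gain parameters: VTs after 2 years'
  gain_has_year1:
    strategy: HAs
    horizon: year1
    mean_dBHL: 4.88
    sd_dBHL: 11.11
    source_ref: 'Table 3, dBHL gain parameters: HAs after 1 year'
  gain_has_year2:
    strategy: HAs
    horizon: year2
    mean_dBHL: 7.57
    sd_dBHL: 12.76
    source_ref: 'Table 3, dBHL gain parameters: HAs after 2 years'
utility:
  mean_per_dBHL: 0.00874
  ci_low: 0.005
  ci_high: 0.012
constants:
  discount_rate: 0.035
  spontaneous_resolution_12m: 0.308
  aom_episodes_per_year: 2.8
  ha_breakage_per_year: 0.1644
  extrusion_weeks: 39.0
  max_insertions: 3
  audiology_visits_per_surgery: 1.5
  ent_visits_per_year_has: 1.5
  cohort_size: 10000
  n_sims: 10000
  ent_visits_per_insertion: 2.0
  audiology_visits_per_year_has: 2.0
  earmould_sets_per_year: 4.0
  battery_sets_per_year: 13.0
  devices_per_child: 2
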