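# Ethiopian annual screening-mammography baseline scenario.
# Sources for every value are listed in ethiopia_baseline_provenance.yaml.
# Age bands 30-39 and 60-69 are retained for completeness (incidence only);
# the analysis age bands are 40-49 and 50-59.
schema_version: 1

age_groups:
  "30-39":
    label: "30-39"
    annual_incidence: 0.000853
  "40-49":
    label: "40-49"
    annual_incidence: 0.000878
    sensitivity: 0.821
    specificity: 0.859
    remaining_life_years:
      "40-44": 36.10367697
      "45-49": 31.72113989
    # Calibrated so that deaths averted x multiplier reproduces the
    # band's life-years gained (2466.14 / 78.55).
    lyg_per_death_averted: 31.39579885423297
  "50-59":
    label: "50-59"
    annual_incidence: 0.00079
    sensitivity: 0.921
    specificity: 0.859
    # No published remaining-life-expectancy value for this band; the
    # life-table LYG mode is therefore unavailable for it.
    remaining_life_years: {}
    # 2566.93 / 107.38
    lyg_per_death_averted: 23.905103371205065
  "60-69":
    label: "60-69"
    annual_incidence: 0.000656

transitions:
  - {stage_group: I,     age_group: "40-49", p_rem_to_local: 0.01,  p_rem_to_dist: 0.000016, p_local_to_dist: 0.062, p_local_to_death: 0.013, p_dist_to_death: 0.555}
  - {stage_group: I,     age_group: "50-59", p_rem_to_local: 0.009, p_rem_to_dist: 0.000025, p_local_to_dist: 0.052, p_local_to_death: 0.013, p_dist_to_death: 0.137}
  # Stages II and III share one printed rate set; no local-recurrence ->
  # cancer-death probability is published for them (kept at 0).
  - {stage_group: II_III, age_group: "40-49", p_rem_to_local: 0.018, p_rem_to_dist: 0.024, p_local_to_dist: 0.165, p_dist_to_death: 0.386}
  - {stage_group: II_III, age_group: "50-59", p_rem_to_local: 0.016, p_rem_to_dist: 0.105, p_local_to_dist: 0.13,  p_dist_to_death: 0.423}
  # Stage IV cases enter the chain in the distant-recurrence state; the only
  # published stage-IV transition is distant recurrence -> cancer death.
  - {stage_group: IV,    age_group: "40-49", p_dist_to_death: 0.386}
  - {stage_group: IV,    age_group: "50-59", p_dist_to_death: 0.423}

stage_distributions:
  # Raw published weights; each arm's weights sum to 1.001 and are
  # proportionally renormalized at load time.
  screened:
    arm: screened
    p_stage: [0.521, 0.382, 0.057, 0.041]
  non_screened:
    arm: non_screened
    p_stage: [0.1, 0.189, 0.569, 0.143]

costs:
  mammography_gov: 4.5
  mammography_private: 42
  doctor_visit: 6
  fnac: 22
  treatment_by_stage: {I: 160, II: 458.48, III: 850.45, IV: 668.7}

discounts:
  cost_rate: 0.05
  effect_rate: 0.03

policy:
  name: government
  private_share: 0.0

cohort_size: 100000
horizon_cycles: 10
cycle_length_years: 1
wtp_threshold: 2808.5
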