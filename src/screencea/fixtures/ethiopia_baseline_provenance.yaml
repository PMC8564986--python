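# Provenance of every value in ethiopia_baseline.yaml: the primary source
# each number originates from, and the uncertainty family assigned to it in
# probabilistic sensitivity analysis.
age_groups:
  annual_incidence:
    source: "Breast cancer incidence by age band extrapolated from Kantelhardt et al. (Ethiopian patient series) combined with national population proportions and WHO cancer data for Ethiopia"
    psa_family: beta
  sensitivity:
    source: "Age-specific screening mammography sensitivity, Keen & Keen (40-49: 0.821; 50-59: 0.921)"
    psa_family: beta
  specificity:
    source: "Age-specific screening mammography specificity, Keen & Keen (0.859 both bands)"
    psa_family: beta
  remaining_life_years:
    source: "WHO life tables for Ethiopia, remaining life expectancy at 40-44 and 45-49"
    psa_family: gamma
  lyg_per_death_averted:
    source: "Calibrated: band life-years gained divided by band deaths averted (2466.14/78.55 and 2566.93/107.38)"
    psa_family: gamma
transitions:
  source: "Stage-specific annual progression probabilities from the Markov screening model of Gocgun et al.; identical rates assumed for screen- and clinically detected cases"
  psa_family: beta
stage_distributions:
  screened:
    source: "Stage at diagnosis among screen-detected cancers, Chinese national screening programme (Wong et al.)"
    psa_family: dirichlet
  non_screened:
    source: "Stage at diagnosis among clinically presenting Ethiopian patients (Tesfaw et al.)"
    psa_family: dirichlet
costs:
  mammography_gov:
    source: "Mean reported government-institution mammography price (direct communication with providers), USD"
    psa_family: fixed
  mammography_private:
    source: "Mean reported private-institution mammography price (direct communication with providers), USD"
    psa_family: fixed
  doctor_visit:
    source: "Mean reported outpatient visit fee (direct communication with providers), USD"
    psa_family: fixed
  fnac:
    source: "Mean reported fine-needle aspiration cytology price (direct communication with providers), USD"
    psa_family: fixed
  treatment_by_stage:
    source: "Stage-specific direct medical treatment cost, Vietnamese costing study (Hoang Lan et al.); stage III cost approximately matches the published mean Ethiopian treatment cost"
    psa_family: gamma
discounts:
  source: "5% annual for costs, 3% annual for life-years"
  psa_family: fixed
wtp_threshold:
  source: "3x GDP per capita for Ethiopia, 2020 World Bank report (2808.5 USD per life-year gained)"
  psa_family: fixed
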