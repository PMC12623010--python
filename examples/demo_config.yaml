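# Demo configuration: the default study conditions.
# Run with:  famrisk run-all --config examples/demo_config.yaml --output-dir famrisk_out
simulation:
  n_founder_couples: 500
  n_generations: 4
  mean_offspring: 2.5
  h2: 0.65              # additive-genetic liability fraction
  c2_couple: 0.10       # shared-couple environment
  c2_sibling: 0.0
  prevalence_female: 0.066
  prevalence_male: 0.024
  p_record_given_affected: 0.9
  p_single_year_noise: 0.02
  p_exclusion_code: 0.01
  birth_year_range: [1920, 2005]
  ehr_years: [1996, 2021]
  seed: 0
policy:
  qualifying_codes: ["245.2", "E06.3", "244.9", "E03.9"]
  exclusionary_codes: ["242.0", "242.9", "E05.0", "E05.9"]
  min_distinct_years: 2
  min_age: 18
  min_relatives: 3
  distinct_year_codes: any_qualifying
matching:
  ratio: 2
  birth_year_window: 2.5
analysis:
  degrees: [1, 2, 3]
  spousal: true
  stratified: true
  estimator: marginal
output_dir: famrisk_out
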