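# Poland case study. Populations inflated from base year 2021; the
# prediabetes prevalence stored here is the effective rate implied by the
# published prevalent-cohort counts (population x 6.8% per band).
name: poland
growth_rate: -0.0031
prediabetes_prevalence: 0.068
reported_prediabetes_prevalence: 0.068
t2d_prevalence: 0.068
age_bands:
  - {label: "20-29", population: 4234204}
  - {label: "30-39", population: 5865052}
  - {label: "40-49", population: 5645197}
  - {label: "50-59", population: 4492238}
  - {label: "60+", population: 9933086}
intervention_costs:
  metformin_per_month: 5.29
  ilc_per_month: 154.40
state_costs:
  normoglycemia_per_year: 1499
  prediabetes_per_year: 1559
  t2d_per_year: 4497
  r_prediabetes: 1.04
  r_t2d: 3.0
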