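# Vietnam case study. As for the other countries the published prevalent
# cohort equals population x 6.8% per band (total 4 722 885); the headline
# 13.8% survey prevalence is kept as metadata only.
name: vietnam
growth_rate: 0.0085
prediabetes_prevalence: 0.068
reported_prediabetes_prevalence: 0.138
t2d_prevalence: 0.059
age_bands:
  - {label: "20-29", population: 14994099}
  - {label: "30-39", population: 16557128}
  - {label: "40-49", population: 13877325}
  - {label: "50-59", population: 11379085}
  - {label: "60+", population: 12646551}
intervention_costs:
  metformin_per_month: 6.26
  ilc_per_month: 160.74
state_costs:
  normoglycemia_per_year: 354
  prediabetes_per_year: 368
  t2d_per_year: 1062
  r_prediabetes: 1.04
  r_t2d: 3.0
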