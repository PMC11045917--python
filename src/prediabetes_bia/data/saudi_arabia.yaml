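# Saudi Arabia case study. The published prevalent-cohort counts equal
# population x 6.8% per band (total 1 682 390), not the headline 12.8%
# survey prevalence; the model uses the effective rate, the headline rate
# is retained as metadata. Disease-state costs are the published values
# (they do not equal normoglycemia x R for this country).
name: saudi_arabia
growth_rate: 0.0150
prediabetes_prevalence: 0.068
reported_prediabetes_prevalence: 0.128
t2d_prevalence: 0.184
age_bands:
  - {label: "20-29", population: 5360331}
  - {label: "30-39", population: 7011184}
  - {label: "40-49", population: 6655298}
  - {label: "50-59", population: 3503340}
  - {label: "60+", population: 2210881}
intervention_costs:
  metformin_per_month: 14.65
  ilc_per_month: 273.88
state_costs:
  normoglycemia_per_year: 1559
  prediabetes_per_year: 2056
  t2d_per_year: 5931
  r_prediabetes: 1.04
  r_t2d: 3.0
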