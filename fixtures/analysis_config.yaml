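# AnalysisConfig / column mapping for `anc-delivery fit`.
# Rename the values to match an external CSV extract's headers.
outcome: place_of_delivery
visits: anc_visits
instrument: first_trimester
items:
  - tetanus
  - weight
  - height
  - blood_pressure
  - urine
  - blood
  - breastfeeding_counsel
  - complication_signs
covariates:
  - residence
  - mother_education
  - wealth_quintile
levels: 3
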