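# Stratified vitamin A income-shock scenario: quartile-specific income
# elasticities applied to quartile intake distributions calibrated to their
# observed baseline deficiency prevalences (EAR cut-point 500 ug RAE/day).
schema_version: 1
seed: 0
rounding: half_away_from_zero
shock:
  driver: income
  pct_change: -15
population: vitamin_a_quartiles.csv
elasticities: vitamin_a_elasticities.csv
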