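# Pooled (single-elasticity) variant of the vitamin A income-shock scenario.
schema_version: 1
seed: 0
rounding: half_away_from_zero
shock:
  driver: income
  pct_change: -15
population: vitamin_a_pooled.csv
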