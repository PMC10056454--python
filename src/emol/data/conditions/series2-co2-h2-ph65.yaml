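name: series2-co2-h2-ph65
vessel:
  total_mL: 300.0
  liquid_mL: 100.0
pressure:
  value: 1.8
  unit: atm
temperature_C: 37.0
gas:
  H2: 75.0
  CO2: 25.0
intermediates:
  butyric acid: 15.0
initial_pH: 6.5
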