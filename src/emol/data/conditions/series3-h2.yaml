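name: series3-h2
vessel:
  total_mL: 300.0
  liquid_mL: 100.0
pressure:
  value: 1.8
  unit: atm
temperature_C: 37.0
gas:
  N2: 78.0
  H2: 22.0
intermediates:
  acetic acid: 39.0
  ethanol: 93.0
initial_pH: 6.5
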