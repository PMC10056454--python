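R1_homoacetogenesis:
  CO2: -2
  H2: -4
  acetic acid: 1
  H2O: 2
R2_co_acetogenesis:
  CO: -4
  H2O: -2
  acetic acid: 1
  CO2: 2
R3_ethanol_from_h2_co2:
  CO2: -2
  H2: -6
  ethanol: 1
  H2O: 3
R4_ethanol_from_co:
  CO: -6
  H2O: -3
  ethanol: 1
  CO2: 4
R5_acetate_reduction:
  acetic acid: -1
  H2: -2
  ethanol: 1
  H2O: 1
R6_elongation_butyrate:
  ethanol: -5
  acetic acid: -3
  butyric acid: 4
  H2: 2
  H2O: 3
R7_elongation_caproate:
  ethanol: -1
  butyric acid: -1
  caproic acid: 1
  H2O: 1
R8_butyrate_reduction:
  butyric acid: -1
  H2: -2
  butanol: 1
  H2O: 1
R9_ethanol_oxidation:
  ethanol: -1
  H2O: -1
  acetic acid: 1
  H2: 2
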