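- name: H2
  formula: H2
  phase: gas
- name: CO
  formula: CO
  phase: gas
- name: CO2
  formula: CO2
  phase: gas
- name: N2
  formula: N2
  phase: gas
  inert: true
- name: H2O
  formula: H2O
  phase: liquid
- name: acetic acid
  formula: C2H4O2
  phase: liquid
- name: ethanol
  formula: C2H6O
  phase: liquid
- name: propionic acid
  formula: C3H6O2
  phase: liquid
- name: butyric acid
  formula: C4H8O2
  phase: liquid
- name: iso-butyric acid
  formula: C4H8O2
  phase: liquid
- name: iso-valeric acid
  formula: C5H10O2
  phase: liquid
- name: caproic acid
  formula: C6H12O2
  phase: liquid
- name: butanol
  formula: C4H10O
  phase: liquid
- name: hexanol
  formula: C6H14O
  phase: liquid
- name: 1,3-propanediol
  formula: C3H8O2
  phase: liquid
  major: false
- name: lactic acid
  formula: C3H6O3
  phase: liquid
  major: false
- name: formic acid
  formula: CH2O2
  phase: liquid
  major: false
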