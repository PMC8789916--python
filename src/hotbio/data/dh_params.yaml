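# Extended Debye-Hueckel (B-dot) coefficients, 0-150 degC, linearly
# interpolated in temperature.  A in (kg/mol)^0.5, B in (kg/mol)^0.5 A^-1
# (ion size in Angstrom), bdot dimensionless.  Standard literature values
# for water at saturation pressure.
debye_huckel:
  temperature_C: [0, 25, 50, 75, 100, 125, 150]
  A: [0.4913, 0.5092, 0.5336, 0.5639, 0.5998, 0.6416, 0.6898]
  B: [0.3247, 0.3283, 0.3325, 0.3371, 0.3422, 0.3476, 0.3533]
  bdot: [0.0374, 0.0410, 0.0440, 0.0460, 0.0470, 0.0470, 0.0460]

# Per-species ion-size parameters (Angstrom) and optional bdot overrides.
# Neutral species (charge 0) use gamma = 10^(bdot * I) with bdot 0.1 unless
# overridden.
species:
  SO4--:   {charge: -2, ion_size_A: 4.0}
  HCO3-:   {charge: -1, ion_size_A: 4.5}
  HS-:     {charge: -1, ion_size_A: 3.5}
  CH3COO-: {charge: -1, ion_size_A: 4.5}
  H+:      {charge: 1, ion_size_A: 9.0}
  CH4:     {charge: 0, ion_size_A: 0.0, bdot: 0.1}
  H2:      {charge: 0, ion_size_A: 0.0, bdot: 0.1}
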