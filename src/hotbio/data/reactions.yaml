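# Catabolic reactions: signed stoichiometry (products +, reactants -) and
# standard-state Gibbs energy at in-situ temperature and pressure.
# dG0_insitu values are INPUT DATA for the reference state below (920 mbsf,
# 100 degC, 55.8 MPa); replace this file to model other states.  The
# acetotrophic values are anchored so that the reference-state dG_R
# reproduces -105 kJ (mol SO4)^-1 and -43 kJ (mol CH4)^-1 exactly; the
# remaining three are representative literature-level values at 100 degC.
reactions:
  AOM:
    stoichiometry: {CH4: -1, SO4--: -1, HCO3-: 1, HS-: 1, H2O: 1}
    dG0_insitu_kj_mol: -25.0
  SR_acetate:
    stoichiometry: {SO4--: -1, CH3COO-: -1, HS-: 1, HCO3-: 2}
    dG0_insitu_kj_mol: -30.587
  SR_H2:
    stoichiometry: {H2: -4, SO4--: -1, H+: -1, HS-: 1, H2O: 4}
    dG0_insitu_kj_mol: -220.0
  MG_acetate:
    stoichiometry: {CH3COO-: -1, H2O: -1, CH4: 1, HCO3-: 1}
    dG0_insitu_kj_mol: -8.432
  MG_H2:
    stoichiometry: {H2: -4, HCO3-: -1, H+: -1, CH4: 1, H2O: 3}
    dG0_insitu_kj_mol: -190.0

# Reference in-situ state: deep sulfate-rich, acetate-rich, DIC-poor zone.
# Sulfide is below detection and takes the 0.1 umol/L floor.
reference_state:
  depth_mbsf: 920.0
  temperature_C: 100.0
  pressure_MPa: 55.8
  ionic_strength: 0.64
  ph: 7.5
  concentrations_mol_l:
    SO4--: 1.0e-2
    CH3COO-: 8.0e-3
    HCO3-: 1.0e-4
    HS-: 0.0
    CH4: 1.0e-3
    H2: 1.3e-7
  below_detection: [HS-]
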