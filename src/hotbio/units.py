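"""Unit conversion constants shared across the package.

Internal canonical units are mol, cm3, g, d, K; interfaces use the field's
customary mixed units (pmol cm-3 d-1, fmol cell-1 d-1, mmol L-1, m2 yr-1).
"""

PMOL_PER_MOL = 1e12
FMOL_PER_MOL = 1e15
FMOL_PER_PMOL = 1e3

ML_PER_L = 1e3
CM3_PER_L = 1e3
MOL_PER_MMOL = 1e-3

#: days per year used to interconvert diffusion (yr) and rate (d) timescales
DAYS_PER_YEAR = 365.25

#: ideal gas constant, kJ mol-1 K-1
R_KJ = 0.008314

CELSIUS_OFFSET = 273.15


def celsius_to_kelvin(t_c: float) -> float:
    return t_c + CELSIUS_OFFSET
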