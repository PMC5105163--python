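"""Physical constants and unit conventions.

All coordinates are in Angstrom, times in ns (trajectories) or minutes
(H/D exchange), energies in kJ/mol unless a function explicitly says
kcal/mol (the restraint module follows the MD convention of its source).
"""

#: Universal gas constant in kJ K^-1 mol^-1.
R_KJ_PER_MOL_K = 0.00831462

#: Default absolute temperature (K) for all thermodynamic conversions.
DEFAULT_TEMPERATURE_K = 310.0

#: Atomic masses (amu) for the elements a pseudo-protein topology may carry.
ELEMENT_MASSES = {
    "H": 1.008,
    "D": 2.014,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "S": 32.06,
    "P": 30.974,
    "F": 18.998,
    "CL": 35.45,
    "NA": 22.990,
    "K": 39.098,
    "MG": 24.305,
    "CA": 40.078,
    "ZN": 65.38,
    "FE": 55.845,
    "SE": 78.971,
}
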